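"""Results serialization and the bubble-plot visualization."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from . import __version__  # noqa: E402
from .errors import FormatError  # noqa: E402
from .inference import RESULT_COLUMNS, AnalysisConfig  # noqa: E402


@dataclass
class ResultsTable:
    """Ordered communication results plus the header needed to reproduce them."""

    table: pd.DataFrame
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    input_digests: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def header_lines(self) -> list[str]:
        cfg = self.config
        lines = [
            f"# metacomm_version={self.version}",
            f"# min_frac_pct={cfg.min_frac_pct:g}",
            f"# n_perm={cfg.n_perm}",
            f"# alpha={cfg.alpha:g}",
            f"# seed={cfg.seed}",
            f"# negative_e_policy={cfg.negative_e_policy}",
            f"# normalization={cfg.normalization}",
            f"# include_autocrine={str(cfg.include_autocrine).lower()}",
        ]
        for name in sorted(self.input_digests):
            lines.append(f"# input_{name}={self.input_digests[name]}")
        return lines


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_results(results: ResultsTable, path: str | Path) -> None:
    """Write a '#'-headered TSV with fixed column order at 6 significant digits."""
    path = Path(path)
    df = results.table
    with path.open("w", encoding="utf-8", newline="") as fh:
        for line in results.header_lines():
            fh.write(line + "\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            cells = []
            for col in RESULT_COLUMNS:
                v = row[col]
                cells.append(_fmt(float(v)) if isinstance(v, (int, float, np.floating)) else str(v))
            fh.write("\t".join(cells) + "\n")


def read_results(path: str | Path) -> ResultsTable:
    """Read a results file back; header keys are restored into the config."""
    path = Path(path)
    header: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            header[key] = val
        else:
            body_start = i
            break
    else:
        raise FormatError(f"{path}: no table body found")
    cols = lines[body_start].split("\t")
    if cols != RESULT_COLUMNS:
        raise FormatError(f"{path}: unexpected column header {cols}")
    records = [ln.split("\t") for ln in lines[body_start + 1 :] if ln]
    df = pd.DataFrame(records, columns=RESULT_COLUMNS)
    for col in ("E", "T", "M", "R", "MR_score", "p_value", "q_value"):
        df[col] = df[col].astype(float)
    config = AnalysisConfig(
        min_frac_pct=float(header.get("min_frac_pct", 10.0)),
        n_perm=int(header.get("n_perm", 100)),
        alpha=float(header.get("alpha", 0.05)),
        seed=int(header.get("seed", 0)),
        negative_e_policy=header.get("negative_e_policy", "literal"),
        normalization=header.get("normalization", "cpm"),
        include_autocrine=header.get("include_autocrine", "true") == "true",
    )
    digests = {
        k[len("input_") :]: v for k, v in header.items() if k.startswith("input_")
    }
    return ResultsTable(table=df, config=config, input_digests=digests)


def bubble_plot(
    table: pd.DataFrame,
    alpha: float,
    path: str | Path,
    size_cap: float = 4.0,
) -> int:
    """Dot plot of significant triples; returns the number of dots drawn.

    x = sender→receiver pair, y = metabolite—receptor pair, dot size
    proportional to −log10(p) (capped), color to MR_score.  When nothing
    passes ``alpha`` an annotated empty figure is still written.
    """
    sig = table[table["p_value"] <= alpha].copy()
    fig, ax = plt.subplots(figsize=(8, 6))
    if sig.empty:
        ax.text(
            0.5,
            0.5,
            f"no interactions with p ≤ {alpha:g}",
            ha="center",
            va="center",
            transform=ax.transAxes,
        )
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return 0
    sig["pair"] = sig["sender"] + "→" + sig["receiver"]
    sig["entry"] = sig["metabolite_name"].where(
        sig["metabolite_name"].astype(bool), sig["metabolite_id"]
    ) + "—" + sig["receptor"]
    xcats = sorted(sig["pair"].unique())
    ycats = sorted(sig["entry"].unique())
    xi = sig["pair"].map({c: i for i, c in enumerate(xcats)})
    yi = sig["entry"].map({c: i for i, c in enumerate(ycats)})
    logp = np.minimum(-np.log10(sig["p_value"].to_numpy()), size_cap)
    sc = ax.scatter(
        xi,
        yi,
        s=30.0 + 120.0 * logp / size_cap,
        c=sig["MR_score"],
        cmap="viridis",
        edgecolors="k",
        linewidths=0.4,
    )
    ax.set_xticks(range(len(xcats)), xcats, rotation=60, ha="right", fontsize=8)
    ax.set_yticks(range(len(ycats)), ycats, fontsize=8)
    ax.set_xlabel("sender → receiver")
    ax.set_ylabel("metabolite — receptor")
    fig.colorbar(sc, ax=ax, label="MR_score")
    ax.margins(0.15)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return len(sig)
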