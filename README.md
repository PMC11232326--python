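# metacomm

Metabolite-mediated cell-cell communication inference from single-cell
expression data.

Given a genes × cells expression matrix (raw counts or TPM), a META table
assigning each cell to a cell type, and a metabolite–receptor knowledgebase,
`metacomm` scores every (sender cell type, receiver cell type, interaction)
triple and assigns empirical significance:

1. **Availability** — per sender, the net enzyme expression
   `E = gmean(producer means) − gmean(consumer means)` and the transporter
   expression `T = gmean(transporter means)` combine into the metabolite
   availability `M = sqrt(E² + T²)`.
2. **Receptor** — per receiver, a receptor complex of q subunits scores
   `R = gmean(subunit means)` (any silent subunit zeroes the complex).
3. **Score** — `MR_score = sqrt(M² + R²)`.
4. **Significance** — one-sided empirical p-values from shuffling cell-type
   labels over all cells and re-running the whole
   profile → filter → score pipeline per permutation
   (`p = (1 + #{permuted MR ≥ observed}) / (n_perm + 1)`), plus
   Benjamini–Hochberg q-values.

Genes expressed in fewer than N% of a cell type's cells are excluded:
enzymes/transporters are filtered against the sender, receptor subunits
against the receiver. All scoring happens on linear (optionally
library-size-normalized) expression; no log transform.

## File formats

* **Expression**: dense TSV (first column gene symbols, header row cell
  names) or a MatrixMarket directory (`matrix.mtx`, `genes.tsv`,
  `barcodes.tsv`).
* **META**: two-column TSV `cell	cell_type` with header.
* **Knowledgebase**: a directory of four TSV tables — `interactions.tsv`
  (metabolite_id, receptor, species, source; complex subunits joined with
  `;`), `enzymes.tsv` (metabolite_id, gene, role ∈ producer/consumer/both),
  `transporters.tsv` (metabolite_id, gene), `metabolites.tsv`
  (metabolite_id, name, hmdb_id, pubchem_cid, class_label).
* **Orthology**: two-column TSV `source_gene	target_gene`.

## CLI

```sh
# generate a synthetic dataset + knowledgebase (null or planted-signal)
metacomm simulate --mode planted --n-metabolites 5 --cells-per-type 50 \
    --seed 0 --out sim/

# run the analysis
metacomm run --expr sim/expression.tsv --meta sim/meta.tsv --kb sim/kb \
    --min-frac-pct 10 --n-perm 1000 --alpha 0.05 --seed 0 --out results/

# knowledgebase utilities
metacomm kb validate sim/kb
metacomm kb summarize sim/kb --out summary.tsv
metacomm kb map-orthologs sim/kb --orthology omap.tsv \
    --target-species mouse --out mouse_kb/

# re-render the bubble plot from a results file
metacomm plot --results results/results.tsv --out bubble.png
```

`run` writes `results.tsv` (a `#`-headered TSV whose header records the tool
version, configuration, and input digests — enough to reproduce the run) and
`bubble.png` (x = sender→receiver, y = metabolite—receptor, dot size
∝ −log10 p, color = MR_score). Exit codes: 0 success, 1 validation/data
error, 2 usage error.

Useful flags for `run`: `--normalize {cpm,tpm,none}` (`tpm` ≡ `none`;
`cpm` rescales each cell to a total of 10,000), `--negative-e
{literal,clamp}` (whether a negative net enzyme expression is squared as-is
or clamped to 0 inside `M`), `--no-autocrine`, `--format {mtx,dense}`.

## Python API

```python
import metacomm as mc

kb = mc.read_kb_dir("sim/kb", species="human")
table = mc.run_analysis("sim/expression.tsv", "sim/meta.tsv", kb,
                        mc.AnalysisConfig(n_perm=999, seed=0))
```

`analyze` is the in-memory equivalent; `score_pass`, `permutation_pvalues`
and `adjust_bh` expose the individual stages, and `metacomm.scoring` holds
the scalar primitives.

## Tests and acceptance report

```sh
python -m pytest -q                 # full suite, < 1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` covers the acceptance criteria: knowledgebase
role-percentage reconstruction, equation fidelity against closed-form
identities, equivalence of the vectorized pipeline with a naive scalar
reference on random fixtures, permutation-test calibration on
label-exchangeable null data, planted-signal recovery across seeds, and
byte-level determinism / degree-1 homogeneity. `scripts/acceptance.py`
recomputes the reported knowledgebase percentages from scratch and writes
them as JSON.
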