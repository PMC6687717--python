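# pubtcr

Public TCR clonotype discovery from bulk and single-cell T-cell receptor
repertoire sequencing.

Severe cutaneous adverse drug reactions (Stevens–Johnson syndrome / toxic
epidermal necrolysis, SJS/TEN) are driven by cytotoxic T lymphocytes that
infiltrate the skin. In carbamazepine-induced SJS/TEN the effector-site
(blister fluid) repertoire is dominated by a *public* TCRβ clonotype — the
same TRBV12-4/TRBJ2-2 rearrangement with CDR3 `ASSLAGELF` expanded in every
patient — paired at the single-cell level with a dominant TCRα CDR3
`VFDNTDKLI`, while the clonotype is undetectable or vanishingly rare
(< 0.001 %) in drug-tolerant and healthy controls. `pubtcr` implements the
complete analysis pipeline behind that kind of discovery, plus a seeded
synthetic-cohort generator so every stage is testable without access to the
raw sequencing data.

## What it computes

- **CDR3 extraction** (`pubtcr.cdr3`): each read is assigned its best
  germline V and J segment by ungapped sliding identity, translated in the
  V-anchored frame, and the CDR3 is taken as all residues strictly between
  the conserved `Y[YFLI]C` motif at the 3′ end of the V segment and the
  `[FW]GXGT` motif of the J segment (anchors excluded). Productive
  junctions are aggregated into per-sample clonotype tables keyed by
  (V gene, J gene, CDR3), with frequencies over productive assigned reads.
- **Repertoire statistics** (`pubtcr.stats`): V/J usage vectors, fold
  change against a control-cohort mean, joint V–J pairing matrices with
  exact marginal consistency, PCA of usage across samples, treemap-style
  ranked exports, and the qPCR clonotype/CD3 ratio `2^(Ct_CD3 − Ct_clone)`
  with its 1e-4 detection floor.
- **Public-clonotype detection** (`pubtcr.public`): a clonotype is public
  iff it reaches ≥ 1 % frequency in all case samples and stays below
  0.001 % in every control (thresholds configurable); plus pairwise
  overlap matrices, one-substitution CDR3 clusters (equal length, Hamming
  distance ≤ 1), and Welch two-sided group contrasts.
- **Single-cell pairing** (`pubtcr.singlecell`): per-β-clonotype α-chain
  pairing percentages and ordered cells × genes expression matrices over a
  functional 18-gene panel.
- **Simulation** (`pubtcr.simulate`): seeded cohorts with heavy-tailed
  background clonotypes, group-specific V/J usage skew, spike-ins planted
  at exact frequencies, read-level output with optional substitution
  errors, and single-cell fixtures — all with recorded ground truth.

## Worked example

```python
from pubtcr import datasets, detect_public
from pubtcr.cdr3 import ClonotypeTable
from pubtcr.simulate import simulate_single_cells
from pubtcr.singlecell import summarize_pairing

# Blister-cell clonotype tables rebuilt from the published read counts of
# the seven carbamazepine-SJS/TEN cases, plus healthy-donor controls that
# lack the shared clonotype.
cases = datasets.blister_case_tables()
controls = [
    ClonotypeTable.from_counts(
        {("TRBV5", "TRBJ1-1", "ASSQQQTDTQY"): 60_000,
         ("TRBV6-1", "TRBJ2-7", "ASSHHHNEQFF"): 40_000},
        sample_id=f"HD{i}")
    for i in range(3)
]
for report in detect_public(cases, controls):
    v, j, cdr3 = report.key
    print(f"public clonotype: {cdr3} ({v}/{j})")
    print(f"  present in {report.n_case_present}/7 cases, "
          f"mean case frequency {100 * report.mean_case_frequency:.2f}%")

summary = summarize_pairing(simulate_single_cells(seed=42))
for row in summary.pairs.itertuples():
    print(f"beta {row.beta_cdr3} + alpha {row.alpha_cdr3}: "
          f"{row.n_cells} cells ({row.percent}%)")
```

prints

```
public clonotype: ASSLAGELF (TRBV12-4/TRBJ2-2)
  present in 7/7 cases, mean case frequency 13.59%
beta ASSLAGELF + alpha VFDNTDKLI: 25 cells (83.33%)
beta ASSLAGELF + alpha AASPPDGNQFY: 4 cells (13.33%)
beta ASSLAGELF + alpha ALDIPNFGNEKLT: 1 cells (3.33%)
```

The detection report says the shared TRBV12-4/TRBJ2-2 `ASSLAGELF`
rearrangement passes the public criteria in all seven blister samples (its
per-case frequencies range from 1.08 % to 42.85 %), and the 30-cell
single-cell fixture resolves its α-chain partners: the dominant
`VFDNTDKLI` in 25/30 cells with two minor partners.

A command-line interface mirrors the library
(`pubtcr simulate | extract | usage | pairing | pca | treemap | public |
cluster | sc-pair | run`); `pubtcr run --config run.toml` executes the full
extract → tabulate → stats → public/cluster pipeline with provenance
headers on every output.

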