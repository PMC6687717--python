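"""Seedable synthetic cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:
heavy-tailed background clonotype abundances (lognormal or power-law),
cohort-specific V/J usage skew, public clonotypes spiked at exact
per-sample frequencies, read-level sequences built as V 3' end + junction
+ J 5' end, and single-cell fixtures with a dominant alpha partner and
elevated cytotoxicity genes.

Construction guarantees make extraction lossless in the no-error regime:
simulated V segments end exactly at the conserved Y[YFLI]C codons, J
segments begin exactly at [FW]GXGT (with X never T, so the motif cannot
form across the junction/J boundary), planted junction nucleotides come
from a fixed one-codon-per-residue table, and background CDR3 peptides are
rejected if they contain a J-style motif or fall within one substitution
of any spike.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cdr3 import ClonotypeTable, J_MOTIF
from .io import (
    CohortDesign,
    GermlineSegment,
    GermlineSet,
    SampleMeta,
    SequenceRead,
    ValidationError,
    write_fasta_reads,
    write_germline_fasta,
    write_sample_sheet,
)
from . import datasets
from .singlecell import DEFAULT_PANEL, SingleCellClone

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# fixed codon per residue, for deterministic junction encoding
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def encode_peptide(aa: str) -> str:
    """Deterministic nucleotide encoding of a peptide."""
    return "".join(CODON[a] for a in aa)


@dataclass(frozen=True)
class SpikeIn:
    """A clonotype planted at exact per-sample/per-group frequencies.

    ``frequencies`` keys may be a sample_id, a full group label
    (cohort|phenotype|drug|tissue), a cohort name, or ``"*"``; the most
    specific match wins and absent keys mean frequency 0.
    """

    v_gene: str
    j_gene: str
    cdr3_aa: str
    frequencies: Mapping[str, float]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class SimulationConfig:
    seed: int
    n_background_clonotypes: int = 5000
    abundance_model: tuple = ("lognormal", 0.0, 1.0)  # or ("power_law", a)
    depth: int | Mapping[str, int] = 100_000
    spike_ins: Sequence[SpikeIn] = field(default_factory=tuple)
    usage_skew: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    error_rate: float = 0.0

    def __post_init__(self):
        depths = (
            [self.depth] if isinstance(self.depth, int) else list(self.depth.values())
        )
        if any(d < 100 for d in depths):
            raise ValidationError("depths must be >= 100")


@dataclass
class RepertoireSim:
    """One simulated sample: planted truth counts and (optionally) reads."""

    sample: SampleMeta
    truth: dict[tuple[str, str, str], int]
    depth: int
    reads: list[SequenceRead] | None = None

    def to_table(self) -> ClonotypeTable:
        """Clonotype table of the exact planted counts.

        In the no-error regime this equals the table obtained by running
        the read-level extraction pipeline on the emitted reads.
        """
        return ClonotypeTable.from_counts(
            self.truth, sample_id=self.sample.sample_id, meta=self.sample
        )


@dataclass
class CohortSim:
    design: CohortDesign
    germline: GermlineSet
    sims: dict[str, RepertoireSim]

    def tables(self, cohort: str | None = None) -> list[ClonotypeTable]:
        metas = (
            self.design.samples
            if cohort is None
            else self.design.by_cohort(cohort)
        )
        return [self.sims[m.sample_id].to_table() for m in metas]


def _resolve(mapping: Mapping[str, object], sample: SampleMeta, default):
    for key in (sample.sample_id, sample.group_label, sample.cohort, "*"):
        if key in mapping:
            return mapping[key]
    return default


# ---------------------------------------------------------------------------
# germline simulation

_SENSE_CODONS = [
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def simulate_germline(
    seed: int,
    n_v: int = 10,
    n_j: int = 5,
    include_reference_names: bool = True,
    v_codons: int = 20,
    j_codons: int = 14,
) -> GermlineSet:
    """Random germline V/J segments with guaranteed junction motifs.

    Every V segment translates in frame 0 and ends with Y[YFLI]C codons;
    every J segment begins with [FW]GXGT codons (X drawn from the 20
    residues minus T). When ``include_reference_names`` is set, the first
    V/J carry the index gene names TRBV12-4 / TRBJ2-2.
    """
    if n_v < 1 or n_j < 1:
        raise ValidationError("need n_v >= 1 and n_j >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    v_segs, j_segs = [], []
    for i in range(n_v):
        body = "".join(rng.choice(_SENSE_CODONS, size=v_codons - 3))
        motif = "TAT" + CODON[str(rng.choice(list("YFLI")))] + "TGT"  # Y?C
        name = (
            "TRBV12-4"
            if include_reference_names and i == 0
            else f"TRBV-sim-{i + 1}"
        )
        v_segs.append(
            GermlineSegment(
                name=name,
                segment_class="V",
                nt_sequence=body + motif,
                reading_frame_offset=0,
            )
        )
    x_choices = [a for a in AA20 if a != "T"]
    for i in range(n_j):
        fw = str(rng.choice(["F", "W"]))
        x = str(rng.choice(x_choices))
        motif = (
            CODON[fw] + CODON["G"] + CODON[x] + CODON["G"] + CODON["T"]
        )
        body = "".join(rng.choice(_SENSE_CODONS, size=j_codons - 5))
        name = (
            "TRBJ2-2"
            if include_reference_names and i == 0
            else f"TRBJ-sim-{i + 1}"
        )
        j_segs.append(
            GermlineSegment(
                name=name,
                segment_class="J",
                nt_sequence=motif + body,
                reading_frame_offset=0,
            )
        )
    return GermlineSet(v_segments=v_segs, j_segments=j_segs)


# ---------------------------------------------------------------------------
# repertoire simulation


def _abundance_weights(rng, model: tuple, n: int) -> np.ndarray:
    kind = model[0]
    if kind == "lognormal":
        mu, sigma = model[1], model[2]
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    if kind == "power_law":
        alpha = model[1]
        return np.arange(1, n + 1, dtype=float) ** (-alpha)
    raise ValidationError(f"unknown abundance model {kind!r}")


def _background_cdr3s(rng, n: int, spikes: Sequence[SpikeIn]) -> list[str]:
    """Random length-8..17 peptides avoiding spike neighbourhoods and
    J-style motifs (which would truncate extraction)."""
    spike_by_len: dict[int, list[str]] = {}
    for s in spikes:
        spike_by_len.setdefault(len(s.cdr3_aa), []).append(s.cdr3_aa)
    out: set[str] = set()
    aa = np.array(list(AA20))
    while len(out) < n:
        length = int(rng.integers(8, 18))
        pep = "".join(rng.choice(aa, size=length))
        if J_MOTIF.search(pep):
            continue
        near_spike = any(
            sum(x != y for x, y in zip(pep, s)) <= 1
            for s in spike_by_len.get(length, ())
        )
        if near_spike:
            continue
        out.add(pep)
    return sorted(out)


def _gene_probs(names: list[str], skew: Mapping[str, float]) -> np.ndarray:
    w = np.array([float(skew.get(n, 1.0)) for n in names])
    return w / w.sum()


def _mutate(rng, nt: str, error_rate: float) -> str:
    arr = np.frombuffer(nt.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if hit.size == 0:
        return nt
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_repertoire(
    config: SimulationConfig,
    sample: SampleMeta,
    germline: GermlineSet,
    emit_reads: bool = True,
    sample_index: int = 0,
) -> RepertoireSim:
    """Simulate one sample's repertoire with exact spike-in counts.

    Spike counts are fixed at round-half-up(frequency x depth); the
    remaining depth is drawn multinomially over background clonotypes
    weighted by the abundance model. Background V/J genes are drawn from
    the skewed usage distribution for the sample's group.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1, int(sample_index)])
    )
    depth = (
        config.depth
        if isinstance(config.depth, int)
        else int(_resolve(config.depth, sample, 100_000))
    )
    spike_freqs = [
        float(_resolve(s.frequencies, sample, 0.0)) for s in config.spike_ins
    ]
    if sum(spike_freqs) >= 1.0:
        raise ValidationError("spike frequencies must sum to < 1")
    spike_counts = [int(np.floor(f * depth + 0.5)) for f in spike_freqs]

    truth: dict[tuple[str, str, str], int] = {}
    for s, c in zip(config.spike_ins, spike_counts):
        if c > 0:
            truth[s.key] = truth.get(s.key, 0) + c

    n_bg = config.n_background_clonotypes
    skew = _resolve(config.usage_skew, sample, {})
    v_names = sorted(s.name for s in germline.v_segments)
    j_names = sorted(s.name for s in germline.j_segments)
    cdr3s = _background_cdr3s(rng, n_bg, list(config.spike_ins))
    bg_v = rng.choice(v_names, size=n_bg, p=_gene_probs(v_names, skew))
    bg_j = rng.choice(j_names, size=n_bg, p=_gene_probs(j_names, skew))
    weights = _abundance_weights(rng, config.abundance_model, n_bg)
    bg_total = depth - sum(spike_counts)
    bg_counts = rng.multinomial(bg_total, weights / weights.sum())
    for cdr3, v, j, c in zip(cdr3s, bg_v, bg_j, bg_counts):
        if c > 0:
            key = (str(v), str(j), cdr3)
            truth[key] = truth.get(key, 0) + int(c)

    reads = None
    if emit_reads:
        reads = []
        i = 0
        for (v, j, cdr3), count in sorted(truth.items()):
            template = (
                germline[v].nt_sequence
                + encode_peptide(cdr3)
                + germline[j].nt_sequence
            )
            for _ in range(count):
                nt = (
                    template
                    if config.error_rate == 0
                    else _mutate(rng, template, config.error_rate)
                )
                reads.append(
                    SequenceRead(
                        read_id=f"{sample.sample_id}:r{i:07d}", nt_sequence=nt
                    )
                )
                i += 1
    return RepertoireSim(sample=sample, truth=truth, depth=depth, reads=reads)


def simulate_cohort(
    config: SimulationConfig,
    design: CohortDesign,
    germline: GermlineSet | None = None,
    out_dir: str | Path | None = None,
    emit_reads: bool = False,
) -> CohortSim:
    """Simulate every sample of a cohort design.

    With ``out_dir`` set, writes germline FASTA, the sample sheet, a truth
    TSV and (when ``emit_reads``) per-sample read FASTAs.
    """
    if germline is None:
        germline = simulate_germline(config.seed, n_v=12, n_j=6)
    sims = {}
    for idx, meta in enumerate(design.samples):
        sims[meta.sample_id] = simulate_repertoire(
            config, meta, germline, emit_reads=emit_reads, sample_index=idx
        )
    cohort = CohortSim(design=design, germline=germline, sims=sims)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_germline_fasta(germline, out / "germline.fasta")
        write_sample_sheet(design, out / "sample_sheet.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("sample_id\tv_gene\tj_gene\tcdr3_aa\tcount\n")
            for sid, sim in sims.items():
                for (v, j, cdr3), c in sorted(sim.truth.items()):
                    fh.write(f"{sid}\t{v}\t{j}\t{cdr3}\t{c}\n")
        if emit_reads:
            reads_dir = out / "reads"
            reads_dir.mkdir(exist_ok=True)
            for sid, sim in sims.items():
                write_fasta_reads(sim.reads, reads_dir / f"{sid}.fasta")
    return cohort


# ---------------------------------------------------------------------------
# study-like presets


def _skew_multiplier(share: float, n_other: int) -> float:
    """Multiplier giving one gene a target share of a uniform background."""
    return share * n_other / (1.0 - share)


def study_cohort_design() -> CohortDesign:
    """Seven blister cases, twelve tolerant and forty-four healthy PBMC."""
    samples = [datasets.case_sample_meta(c) for c in range(1, 8)]
    samples += [
        SampleMeta(
            sample_id=f"T{i}", cohort="tolerant", phenotype="tolerant",
            drug="CBZ", tissue="PBMC", hla_flag=i <= 6,
        )
        for i in range(1, 13)
    ]
    samples += [
        SampleMeta(
            sample_id=f"H{i}", cohort="healthy", phenotype="healthy",
            drug="", tissue="PBMC", hla_flag=False,
        )
        for i in range(1, 45)
    ]
    return CohortDesign(samples=samples)


def study_cohort_config(
    seed: int,
    depth: int = 100_000,
    n_background: int = 5000,
    error_rate: float = 0.0,
    n_v: int = 12,
    n_j: int = 6,
) -> SimulationConfig:
    """Cohort preset: the public clonotype spiked at the seven reported
    per-case frequencies (zero in controls) and case V/J usage skewed so
    cohort-mean TRBV12-4 / TRBJ2-2 usage matches the reported blister
    means."""
    spike = SpikeIn(
        v_gene=datasets.PUBLIC_BETA_V,
        j_gene=datasets.PUBLIC_BETA_J,
        cdr3_aa=datasets.PUBLIC_BETA_CDR3,
        frequencies={
            f"BC{case}": f
            for case, f in datasets.PUBLIC_CASE_FREQUENCIES.items()
        },
    )
    mean_spike = float(np.mean(list(datasets.PUBLIC_CASE_FREQUENCIES.values())))
    v_share = (datasets.TRBV12_4_BLISTER_MEAN - mean_spike) / (1 - mean_spike)
    j_share = (datasets.TRBJ2_2_BLISTER_MEAN - mean_spike) / (1 - mean_spike)
    case_skew = {
        datasets.PUBLIC_BETA_V: _skew_multiplier(v_share, n_v - 1),
        datasets.PUBLIC_BETA_J: _skew_multiplier(j_share, n_j - 1),
    }
    return SimulationConfig(
        seed=seed,
        n_background_clonotypes=n_background,
        depth=depth,
        spike_ins=(spike,),
        usage_skew={"case": case_skew},
        error_rate=error_rate,
    )


def study_cohort(
    seed: int,
    depth: int = 100_000,
    n_background: int = 5000,
    error_rate: float = 0.0,
    out_dir: str | Path | None = None,
    emit_reads: bool = False,
) -> CohortSim:
    """Simulate the full study-like cohort (7 + 12 + 44 samples)."""
    config = study_cohort_config(
        seed, depth=depth, n_background=n_background, error_rate=error_rate
    )
    return simulate_cohort(
        config,
        study_cohort_design(),
        out_dir=out_dir,
        emit_reads=emit_reads,
    )


def blister_sample_config(
    seed: int,
    depth: int = 10_000,
    n_background: int = 2000,
    error_rate: float = 0.0,
    n_v: int = 10,
    n_j: int = 5,
) -> tuple[SimulationConfig, SampleMeta]:
    """Single blister-like sample preset.

    Plants the public clonotype at its cohort-mean frequency together with
    two further TRBV12-4 expansions (the clonal expansions are what drive
    the V-usage skew in real blister repertoires), and skews the background
    so expected TRBV12-4 usage matches the reported blister mean.
    """
    mean_pub = float(np.mean(list(datasets.PUBLIC_CASE_FREQUENCIES.values())))
    spikes = (
        SpikeIn("TRBV12-4", "TRBJ2-2", datasets.PUBLIC_BETA_CDR3,
                {"*": round(mean_pub, 4)}),
        SpikeIn("TRBV12-4", "TRBJ-sim-2", "ASSLSDTIY", {"*": 0.10}),
        SpikeIn("TRBV12-4", "TRBJ2-2", "ASTHTGELF", {"*": 0.046}),
    )
    spike_total = sum(float(s.frequencies["*"]) for s in spikes)
    v_share = (datasets.TRBV12_4_BLISTER_MEAN - spike_total) / (1 - spike_total)
    config = SimulationConfig(
        seed=seed,
        n_background_clonotypes=n_background,
        abundance_model=("lognormal", 0.0, 0.8),
        depth=depth,
        spike_ins=spikes,
        usage_skew={"*": {"TRBV12-4": _skew_multiplier(v_share, n_v - 1)}},
        error_rate=error_rate,
    )
    meta = SampleMeta(
        sample_id="BCsim", cohort="case", phenotype="SJS/TEN",
        drug="CBZ", tissue="blister", hla_flag=True,
    )
    return config, meta


# ---------------------------------------------------------------------------
# single-cell simulation


def simulate_single_cells(
    seed: int,
    n_cells: int = 30,
    pairing_profile: Mapping[str, int] | None = None,
    panel: Sequence[str] = DEFAULT_PANEL,
    beta_cdr3: str = datasets.PUBLIC_BETA_CDR3,
    elevated_genes: Sequence[str] = ("GNLY", "GZMB"),
    baseline_mean: float = 4.0,
    elevated_mean: float = 45.0,
) -> list[SingleCellClone]:
    """Simulate sorted single cells sharing one beta clonotype.

    The default pairing profile mirrors the 30-cell experiment (alpha
    split 25/4/1 under one beta); other cell numbers default to a single
    alpha partner. Panel expression is negative-binomial with planted
    elevation of the cytotoxicity genes.
    """
    if pairing_profile is None:
        if n_cells == datasets.SINGLE_CELL_N:
            pairing_profile = dict(datasets.SINGLE_CELL_ALPHA_PROFILE)
        else:
            pairing_profile = {datasets.PUBLIC_ALPHA_CDR3: n_cells}
    if sum(pairing_profile.values()) != n_cells:
        raise ValidationError("pairing profile counts must sum to n_cells")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    alphas = [a for a, n in pairing_profile.items() for _ in range(n)]
    nb_shape = 2.0
    cells = []
    for i, alpha in enumerate(alphas):
        counts = {}
        for g in panel:
            mean = elevated_mean if g in elevated_genes else baseline_mean
            counts[g] = int(
                rng.negative_binomial(nb_shape, nb_shape / (nb_shape + mean))
            )
        cells.append(
            SingleCellClone(
                cell_id=f"cell{i + 1:03d}",
                beta_cdr3=beta_cdr3,
                alpha_cdr3=alpha,
                beta_v=datasets.PUBLIC_BETA_V,
                beta_j=datasets.PUBLIC_BETA_J,
                alpha_v="TRAV-sim-1",
                alpha_j="TRAJ-sim-1",
                gene_counts=counts,
            )
        )
    return cells
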