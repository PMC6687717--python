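"""Published reference values for the carbamazepine-SJS/TEN public TCR.

The deep-sequencing study of blister-cell repertoires from seven
carbamazepine-induced SJS/TEN patients reported, per case, the dominant
TCRbeta clonotypes with their read counts and totals, a shared
("public") TRBV12-4/TRBJ2-2 rearrangement with CDR3 ``ASSLAGELF`` in every
case, and a 30-cell single-cell experiment resolving its alpha-chain
partners. These printed values are inputs to fixture construction and to
the acceptance computations; everything derived from them (frequencies,
detection flags, pairing percentages) is computed by the package at run
time.
"""
from __future__ import annotations

from .cdr3 import ClonotypeTable
from .io import SampleMeta

PUBLIC_BETA_V = "TRBV12-4"
PUBLIC_BETA_J = "TRBJ2-2"
PUBLIC_BETA_CDR3 = "ASSLAGELF"
PUBLIC_BETA_KEY = (PUBLIC_BETA_V, PUBLIC_BETA_J, PUBLIC_BETA_CDR3)

PUBLIC_ALPHA_CDR3 = "VFDNTDKLI"

# Cohort-level V/J usage means in blister cells of the seven cases
# (fractions); used as synthetic-generator targets only — they depend on
# the deposited raw data and are not desk-reproducible.
TRBV12_4_BLISTER_MEAN = 0.3162
TRBJ2_2_BLISTER_MEAN = 0.2215

# Total TCRbeta reads per blister sample, cases 1-7.
CASE_TOTAL_READS = {
    1: 746406,
    2: 792164,
    3: 81449,
    4: 72692,
    5: 822649,
    6: 1229012,
    7: 798017,
}

# Reported dominant clonotypes per case: (cdr3_aa, v_gene, j_gene, reads).
CASE_CLONOTYPES: dict[int, list[tuple[str, str, str, int]]] = {
    1: [
        ("ASSLSDTIY", "TRBV12-4", "TRBJ1-3", 182480),
        ("ASSLGGAPY", "TRBV12-4", "TRBJ2-7", 62776),
        ("ASSYNPGTGTEEYEQY", "TRBV6-1", "TRBJ2-7", 48516),
        ("ASTHTGELF", "TRBV12-4", "TRBJ2-2", 34325),
        ("ASSLAGELF", "TRBV12-4", "TRBJ2-2", 27829),
        ("ASSPRLAGSTDTQY", "TRBV27", "TRBJ2-3", 15748),
    ],
    2: [
        ("ASSLAGELF", "TRBV12-4", "TRBJ2-2", 153620),
        ("ASSLSGYEQY", "TRBV27", "TRBJ2-7", 31781),
        ("ASSSAGEVF", "TRBV12-4", "TRBJ2-1", 17990),
    ],
    3: [
        ("ASSLAGELF", "TRBV12-4", "TRBJ2-2", 5411),
        ("ATSGPNQETQY", "TRBV24-1", "TRBJ2-5", 1697),
    ],
    4: [
        ("ASSLAGELF", "TRBV12-4", "TRBJ2-2", 31148),
        ("ASSYRDGYEQY", "TRBV6-5", "TRBJ2-7", 1986),
        ("ASSRRAVVGSYNEQF", "TRBV7-2", "TRBJ2-1", 1905),
        ("ATHGTGYLEQY", "TRBV25-1", "TRBJ2-7", 1565),
    ],
    5: [
        ("ASSLAGELF", "TRBV12-4", "TRBJ2-2", 143248),
        ("ASSSRLAGGTDTQY", "TRBV27", "TRBJ2-3", 99586),
    ],
    6: [
        ("ASSPSDRSSYEQY", "TRBV18", "TRBJ2-7", 57694),
        ("ASSSLTSSWVEQF", "TRBV28", "TRBJ2-1", 46784),
        ("ASTSGPNEQF", "TRBV12-4", "TRBJ2-1", 36759),
        ("ASSYSSTDTQY", "TRBV6-5", "TRBJ2-3", 34429),
        ("ASSQYRYNEQF", "TRBV14", "TRBJ2-1", 32006),
        ("ASSFAGELF", "TRBV12-4", "TRBJ2-2", 27338),
        ("ASSLAGELF", "TRBV12-4", "TRBJ2-2", 13273),
    ],
    7: [
        ("ASSWDPTIY", "TRBV12-3", "TRBJ1-3", 81449),
        ("ASSLAGELF", "TRBV12-4", "TRBJ2-2", 31881),
        ("ASIDGSSLNEQF", "TRBV27", "TRBJ2-1", 28498),
        ("ASSLSGYEQY", "TRBV27", "TRBJ2-7", 23122),
        ("ASSYSDTIY", "TRBV6-6", "TRBJ1-3", 19948),
    ],
}

CASE_PHENOTYPES = {
    1: "SJS/TEN", 2: "SJS", 3: "SJS", 4: "TEN", 5: "SJS/TEN",
    6: "SJS/TEN", 7: "TEN",
}

# Reported public-clonotype read fractions per case, used as the per-sample
# spike-in frequencies of the study-like synthetic cohort.
PUBLIC_CASE_FREQUENCIES = {
    case: next(
        n for cdr3, _v, _j, n in rows if cdr3 == PUBLIC_BETA_CDR3
    ) / CASE_TOTAL_READS[case]
    for case, rows in CASE_CLONOTYPES.items()
}

# Single-cell alpha-chain partners of the public beta clonotype: 30 sorted
# cells, all beta ASSLAGELF, alpha split 25/4/1.
SINGLE_CELL_N = 30
SINGLE_CELL_ALPHA_PROFILE = {
    "VFDNTDKLI": 25,
    "AASPPDGNQFY": 4,
    "ALDIPNFGNEKLT": 1,
}

# Unique per-case filler CDR3s for the unreported remainder of each
# repertoire (length 11, well away from the public length-9 cluster).
_FILLER_CDR3 = {
    1: "ASSGQANTEAF",
    2: "ASSGQCNTEAF",
    3: "ASSGQDNTEAF",
    4: "ASSGQENTEAF",
    5: "ASSGQHNTEAF",
    6: "ASSGQKNTEAF",
    7: "ASSGQMNTEAF",
}


def case_sample_meta(case: int) -> SampleMeta:
    return SampleMeta(
        sample_id=f"BC{case}",
        cohort="case",
        phenotype=CASE_PHENOTYPES[case],
        drug="CBZ",
        tissue="blister",
        hla_flag=True,
    )


def blister_case_table(case: int) -> ClonotypeTable:
    """Clonotype table replicating one case's printed read counts.

    The reported clonotypes keep their exact counts; the remainder of the
    total read count is carried by a single synthetic filler clonotype so
    the reported frequencies are reproduced exactly.
    """
    rows = CASE_CLONOTYPES[case]
    total = CASE_TOTAL_READS[case]
    counts = {(v, j, cdr3): n for cdr3, v, j, n in rows}
    remainder = total - sum(counts.values())
    counts[("TRBV28", "TRBJ1-1", _FILLER_CDR3[case])] = remainder
    return ClonotypeTable.from_counts(
        counts, sample_id=f"BC{case}", meta=case_sample_meta(case)
    )


def blister_case_tables() -> list[ClonotypeTable]:
    """The seven blister-cell case tables."""
    return [blister_case_table(c) for c in sorted(CASE_CLONOTYPES)]
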