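"""One-shot pipeline: extract -> tabulate -> stats -> public/cluster.

Configuration is a flat ``key = value`` text file (CLI flags override file
values); every output TSV carries a provenance header with the package
version, a hash of the effective configuration and the seed, so a rerun
into a clean directory reproduces byte-identical artifacts.
"""
from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cdr3 import build_clonotype_table
from .io import (
    ValidationError,
    read_fasta_reads,
    read_germline_fasta,
    read_sample_sheet,
    write_rearrangement_tsv,
)
from .public import (
    DEFAULT_MAX_CONTROL_FREQ,
    DEFAULT_MIN_CASE_FRACTION,
    DEFAULT_MIN_CASE_FREQ,
    cdr3_cluster,
    detect_public,
    pairwise_overlap,
)
from .stats import cohort_mean_pairing, usage_pca, usage_vector, vj_pairing_matrix

log = logging.getLogger("pubtcr")


@dataclass
class PipelineConfig:
    germline: str
    reads_dir: str
    sample_sheet: str
    out_dir: str
    min_identity: float = 0.9
    min_case_fraction: float = DEFAULT_MIN_CASE_FRACTION
    min_case_freq: float = DEFAULT_MIN_CASE_FREQ
    max_control_freq: float = DEFAULT_MAX_CONTROL_FREQ
    cluster_seed: str = ""  # empty: use the top public CDR3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("germline", "reads_dir", "sample_sheet"):
            if not Path(getattr(self, name)).exists():
                raise ValidationError(f"{name} path does not exist: "
                                      f"{getattr(self, name)}")
        if not 0 < self.min_identity <= 1:
            raise ValidationError("min_identity must be in (0, 1]")
        for name in ("min_case_fraction", "min_case_freq", "max_control_freq"):
            if not 0 <= float(getattr(self, name)) <= 1:
                raise ValidationError(f"{name} out of range")

    def config_hash(self) -> str:
        # output location and logging verbosity are not analysis parameters
        skip = {"out_dir", "log_level"}
        payload = "\n".join(
            f"{k}={v}" for k, v in sorted(asdict(self).items()) if k not in skip
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def parse_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse a flat ``key = value`` config file; kwargs override file values."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"config line without '=': {line!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        values[k] = v.strip("\"'")
    values.update({k: v for k, v in overrides.items() if v is not None})
    fields = PipelineConfig.__dataclass_fields__
    unknown = set(values) - set(fields)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    typed = {}
    for k, v in values.items():
        typ = fields[k].type
        if typ == "float":
            typed[k] = float(v)
        elif typ == "int":
            typed[k] = int(v)
        else:
            typed[k] = str(v)
    return PipelineConfig(**typed)


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict
    public_report: list
    outputs: dict[str, Path] = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> Path:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    chash = config.config_hash()
    header = f"# pubtcr={__version__} config={chash} seed={config.seed}\n"
    log_lines = [f"pubtcr {__version__} config={chash} seed={config.seed}"]

    def stage(name):
        log.info("stage %s", name)
        log_lines.append(f"stage={name} t={time.strftime('%H:%M:%S')}")

    outputs: dict[str, Path] = {}
    try:
        stage("ingest")
        germline = read_germline_fasta(config.germline)
        design = read_sample_sheet(config.sample_sheet)
        for name in ("germline", "sample_sheet"):
            digest = hashlib.sha256(
                Path(getattr(config, name)).read_bytes()
            ).hexdigest()[:12]
            log_lines.append(f"input={name} sha256={digest}")

        stage("extract")
        tables = {}
        tables_dir = out / "tables"
        tables_dir.mkdir(exist_ok=True)
        for meta in design.samples:
            reads_path = Path(config.reads_dir) / f"{meta.sample_id}.fasta"
            if not reads_path.exists():
                raise ValidationError(f"missing reads file: {reads_path}")
            reads = read_fasta_reads(reads_path)
            table = build_clonotype_table(
                reads, germline, meta, min_identity=config.min_identity
            )
            tables[meta.sample_id] = table
            write_rearrangement_tsv(table, tables_dir / f"{meta.sample_id}.tsv")

        stage("stats")
        usage_rows = []
        v_usages = {}
        for sid, table in tables.items():
            for axis in ("V", "J"):
                u = usage_vector(table, axis)
                if axis == "V":
                    v_usages[sid] = u
                for gene, f in u.entries.items():
                    usage_rows.append(
                        {"sample_id": sid, "axis": axis, "gene": gene,
                         "frequency": f}
                    )
        outputs["usage"] = _write_tsv(
            pd.DataFrame(usage_rows), out / "usage.tsv", header
        )
        case_ids = [m.sample_id for m in design.by_cohort("case")]
        if case_ids:
            mean_pairing = cohort_mean_pairing(
                [vj_pairing_matrix(tables[s]) for s in case_ids]
            )
            outputs["pairing"] = _write_tsv(
                mean_pairing.to_links(), out / "pairing_case_mean.tsv", header
            )
        if len(tables) >= 2:
            k = min(2, len(v_usages) - 1,
                    len({g for u in v_usages.values() for g in u.entries.index}))
            pca = usage_pca(v_usages, k=k)
            scores = pca.scores.reset_index(names="sample_id")
            outputs["pca"] = _write_tsv(scores, out / "pca_scores.tsv", header)

        stage("public")
        case_tables = [tables[s] for s in case_ids]
        control_tables = [
            tables[m.sample_id]
            for m in design.samples
            if m.cohort != "case"
        ]
        public = []
        if case_tables and control_tables:
            public = detect_public(
                case_tables,
                control_tables,
                min_case_fraction=config.min_case_fraction,
                min_case_freq=config.min_case_freq,
                max_control_freq=config.max_control_freq,
            )
            pub_rows = [
                {
                    "v_gene": r.key[0], "j_gene": r.key[1],
                    "cdr3_aa": r.key[2], "n_case_present": r.n_case_present,
                    "mean_case_frequency": r.mean_case_frequency,
                    "control_max_frequency": r.control_max_frequency,
                }
                for r in public
            ]
            outputs["public"] = _write_tsv(
                pd.DataFrame(
                    pub_rows,
                    columns=["v_gene", "j_gene", "cdr3_aa", "n_case_present",
                             "mean_case_frequency", "control_max_frequency"],
                ),
                out / "public.tsv", header,
            )
            if len(case_tables) >= 2:
                outputs["overlap"] = _write_tsv(
                    pairwise_overlap(case_tables).to_links(),
                    out / "overlap_cases.tsv", header,
                )

        stage("cluster")
        seed_cdr3 = config.cluster_seed or (
            public[0].key[2] if public else ""
        )
        if seed_cdr3:
            cl_rows = []
            for sid in case_ids:
                cl = cdr3_cluster(seed_cdr3, tables[sid])
                for m in cl.members.itertuples():
                    cl_rows.append(
                        {"sample_id": sid, "seed": seed_cdr3,
                         "cdr3_aa": m.cdr3_aa, "count": m.count,
                         "frequency": m.frequency, "distance": m.distance}
                    )
                cl_rows.append(
                    {"sample_id": sid, "seed": seed_cdr3, "cdr3_aa": "TOTAL",
                     "count": int(cl.members["count"].sum()) if len(cl.members) else 0,
                     "frequency": cl.cluster_frequency, "distance": -1}
                )
            outputs["cluster"] = _write_tsv(
                pd.DataFrame(cl_rows), out / "cluster.tsv", header
            )
    except Exception as exc:
        log_lines.append(f"FAILED: {type(exc).__name__}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    stage("done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        config=config, tables=tables, public_report=public, outputs=outputs
    )
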