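"""Report assembly: run the analysis stages in order and write a bundle.

Every output file starts with provenance comment lines (tool version,
seed, SHA-256 of each input) and all tables use stable sort orders, so
two runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .anthro import LMSReference, classify_weight_status
from .core import CNVCall, CohortConfig, LocusCatalogEntry, PatientRecord
from .genes import genes_overlapped, prioritize
from .intervals import assign_to_catalog, cluster_by_overlap, recurrent_loci
from .io import read_gene_set, read_gene_table
from .phenstats import build_network, pair_matrix
from .tally import tally
from .validate import validate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    out_dir: Path
    cohort_path: Optional[Path] = None
    calls_path: Optional[Path] = None
    catalog_path: Optional[Path] = None
    gene_table_path: Optional[Path] = None
    gene_set_paths: dict[str, Path] = field(default_factory=dict)
    n_cohort: Optional[int] = None
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    skip: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        inputs = {
            p.resolve()
            for p in (
                self.cohort_path, self.calls_path, self.catalog_path,
                self.gene_table_path, *self.gene_set_paths.values(),
            )
            if p is not None
        }
        if self.out_dir.resolve() in {p.parent for p in inputs}:
            # outputs may share a directory with inputs but never a name;
            # checked again per file on write
            pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _provenance(config: RunConfig) -> list[str]:
    lines = [f"# cnvcohort {__version__}", f"# seed: {config.seed}"]
    for label, path in (
        ("cohort", config.cohort_path),
        ("calls", config.calls_path),
        ("catalog", config.catalog_path),
        ("genes", config.gene_table_path),
    ):
        if path is not None:
            lines.append(f"# input {label}: {Path(path).name} sha256={_sha256(path)}")
    return lines


def _write_table(df: pd.DataFrame, path: Path, provenance: list[str]) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(
    config: RunConfig,
    patients: Optional[Sequence[PatientRecord]] = None,
    cnvs: Optional[Sequence[CNVCall]] = None,
    catalog: Optional[Sequence[LocusCatalogEntry]] = None,
    lms_refs: Optional[dict[str, LMSReference]] = None,
) -> dict[str, Path]:
    """Execute validate -> tally -> recurrence/SRO -> anthropometry ->
    phenotype stats -> prioritization; returns {artifact name: path}.

    In-memory inputs take precedence over paths in ``config``; unset
    inputs default to the packaged fixtures.
    """
    from . import resources
    from .io import read_cnv_table, read_cohort_table, read_locus_catalog

    out: dict[str, Path] = {}
    config.out_dir.mkdir(parents=True, exist_ok=True)
    if patients is None:
        patients = (
            read_cohort_table(config.cohort_path)
            if config.cohort_path
            else resources.load_pcnv_patients()
        )
    if cnvs is None:
        cnvs = (
            read_cnv_table(config.calls_path)
            if config.calls_path
            else resources.load_pcnv_calls()
        )
    if catalog is None:
        catalog = (
            read_locus_catalog(config.catalog_path)
            if config.catalog_path
            else resources.load_locus_catalog()
        )
    prov = _provenance(config)
    cfg = config.cohort_config

    report = validate_cohort(patients, cnvs, cfg)
    if not report.ok:
        raise PipelineError("validate", report.summary())

    if "tally" not in config.skip:
        t = tally(patients, cnvs, catalog, cfg, n_cohort=config.n_cohort)
        df = pd.DataFrame(t.to_rows())
        path = config.out_dir / "tally.tsv"
        _write_table(df, path, prov)
        out["tally"] = path
        jpath = config.out_dir / "tally.json"
        jpath.write_text(json.dumps(
            {r["entry"]: {k: v for k, v in r.items() if k != "entry"}
             for r in t.to_rows()},
            indent=2, sort_keys=True) + "\n")
        out["tally_json"] = jpath

    if "recurrence" not in config.skip:
        pathogenic = [c for c in cnvs if c.is_pathogenic]
        known = [e for e in catalog if e.known_genomic_disorder]
        assignments, unassigned = assign_to_catalog(
            pathogenic, known, cfg.min_overlap_bp
        )
        rec = recurrent_loci(assignments, min_patients=2)
        _write_table(
            pd.DataFrame(rec, columns=["locus_id", "n_patients"]),
            config.out_dir / "recurrent_loci.tsv", prov,
        )
        out["recurrent_loci"] = config.out_dir / "recurrent_loci.tsv"

        clusters = cluster_by_overlap(pathogenic, ignore_type=True)
        rows = []
        for c in clusters:
            rows.append({
                "cluster_id": c.cluster_id,
                "chrom": c.span.chrom,
                "span_start": c.span.start,
                "span_end": c.span.end,
                "n_calls": len(c.members),
                "n_patients": c.n_patients,
                "sro_start": c.sro.start if c.sro else "",
                "sro_end": c.sro.end if c.sro else "",
                "sro_len": c.sro.length if c.sro else 0,
            })
        _write_table(pd.DataFrame(rows), config.out_dir / "clusters.tsv", prov)
        out["clusters"] = config.out_dir / "clusters.tsv"

    if "anthropometry" not in config.skip:
        if lms_refs is None:
            try:
                lms_refs = resources.load_lms_references()
            except Exception as exc:  # pragma: no cover - packaged data exists
                raise PipelineError("anthropometry", str(exc)) from exc
        rows = []
        for p in sorted(patients, key=lambda p: p.patient_id):
            try:
                res = classify_weight_status(p, lms_refs, cfg)
            except Exception as exc:
                raise PipelineError(
                    "anthropometry", f"patient {p.patient_id}: {exc}"
                ) from exc
            rows.append({
                "patient_id": p.patient_id,
                "age_months": p.age_months,
                "sex": p.sex.value,
                "category": res.category.value,
                "zscore": "" if res.zscore is None else f"{res.zscore:.4f}",
                "percentile": "" if res.percentile is None else f"{res.percentile:.2f}",
                "pct_of_95th": "" if res.pct_of_95th is None else f"{res.pct_of_95th:.1f}",
            })
        _write_table(pd.DataFrame(rows), config.out_dir / "severity.tsv", prov)
        out["severity"] = config.out_dir / "severity.tsv"

    features = sorted({f for p in patients for f in p.phenotypes})
    if "phenet" not in config.skip and len(features) >= 2:
        matrix = pair_matrix(list(patients), features)
        _write_table(
            matrix.to_long_frame(), config.out_dir / "pair_matrix.tsv", prov
        )
        out["pair_matrix"] = config.out_dir / "pair_matrix.tsv"
        network = build_network(matrix, alpha=cfg.pair_alpha)
        edges = pd.DataFrame(network.edges, columns=["feature_a", "feature_b", "p"])
        _write_table(edges, config.out_dir / "network_edges.tsv", prov)
        out["network_edges"] = config.out_dir / "network_edges.tsv"

    if (
        "prioritize" not in config.skip
        and config.gene_table_path is not None
        and config.gene_set_paths
    ):
        genes = read_gene_table(config.gene_table_path)
        sets = {name: read_gene_set(p) for name, p in config.gene_set_paths.items()}
        hits = genes_overlapped(list(cnvs), genes)
        evidence = prioritize(hits, sets)
        rows = [
            {
                "symbol": e.symbol,
                "n_sets": e.n_sets,
                "sets": ",".join(e.sets),
                "patients": ",".join(sorted({p for p, _ in e.within})),
                "prioritized": int(e.prioritized),
            }
            for e in evidence
        ]
        _write_table(pd.DataFrame(rows), config.out_dir / "prioritized_genes.tsv", prov)
        out["prioritized_genes"] = config.out_dir / "prioritized_genes.tsv"
    return out
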