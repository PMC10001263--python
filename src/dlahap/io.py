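"""TSV file formats, run configuration and the analysis pipeline.

All tables are UTF-8, tab-separated, Unix newlines.  Writers prepend
``# key=value`` comment lines carrying the config hash and seed so any
output can be traced to the run that produced it; readers skip comment
lines.  The genotype table has one row per dog::

    dog_id  breed  a88_1  a88_2  a12_88L_1  a12_88L_2  drb1_1  drb1_2

with allele tokens in the nomenclature grammar, sublocus prefixes
(``88*``, ``12*``, ``88L*``, ``DRB1*``) legal per column, and missing
calls as ``NA`` (both alleles of a pair or neither).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import math
import pandas as pd
import yaml

from . import diversity as _div
from . import matching as _match
from . import structure as _struct
from .nomenclature import AlleleName, HaplotypeLabel, parse_allele, parse_haplotype
from .phasing import (
    Diplotype,
    DogGenotype,
    DogPhase,
    PhasingResult,
    em_phase,
    phase_cohort,
)
from .simulate import SimConfig, TrueCohort, simulate_cohort

__all__ = [
    "GENOTYPE_COLUMNS",
    "RunConfig",
    "PipelineError",
    "PipelineResult",
    "read_genotypes",
    "write_genotypes",
    "write_truth",
    "write_phasing",
    "read_phasing",
    "run_pipeline",
]

logger = logging.getLogger("dlahap")

GENOTYPE_COLUMNS = [
    "dog_id",
    "breed",
    "a88_1",
    "a88_2",
    "a12_88L_1",
    "a12_88L_2",
    "drb1_1",
    "drb1_2",
]

_SLOT_HINTS = {
    ("a88_1", "a88_2"): ("88",),
    ("a12_88L_1", "a12_88L_2"): ("12", "88L"),
    ("drb1_1", "drb1_2"): ("DRB1",),
}


# ---------------------------------------------------------------------
# low-level TSV helpers


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------
# genotype tables


def _parse_pair(
    row: dict, cols: tuple[str, str], hints: tuple[str, ...], line: int
) -> tuple[AlleleName, AlleleName] | None:
    raw = [row[c].strip() for c in cols]
    na = [r.upper() == "NA" or r == "" for r in raw]
    if all(na):
        return None
    if any(na):
        raise ValueError(
            f"line {line}: columns {cols[0]}/{cols[1]} must both be set or both NA"
        )
    out = []
    for c, r in zip(cols, raw, strict=True):
        allele = parse_allele(r)
        if allele.locus not in hints:
            raise ValueError(
                f"line {line}: allele {r!r} illegal in column {c} "
                f"(expected locus in {hints})"
            )
        out.append(allele)
    return tuple(out)  # type: ignore[return-value]


def read_genotypes(path: str | Path) -> list[DogGenotype]:
    """Read a genotype TSV; dogs with any NA locus are excluded (logged)."""
    path = Path(path)
    df = _read_tsv(path)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing genotype columns {missing}")
    out: list[DogGenotype] = []
    n_na = 0
    for idx, row in enumerate(df.to_dict("records")):
        line = idx + 2  # header is line 1
        try:
            pairs = [
                _parse_pair(row, cols, hints, line)
                for cols, hints in _SLOT_HINTS.items()
            ]
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from e
        if any(p is None for p in pairs):
            n_na += 1
            continue
        out.append(
            DogGenotype.from_alleles(row["dog_id"], row["breed"], *pairs)
        )
    if n_na:
        logger.info("%s: excluded %d dogs with missing calls", path.name, n_na)
    return out


def write_genotypes(
    genotypes: list[DogGenotype], path: str | Path, meta: dict | None = None
) -> None:
    rows = []
    for g in genotypes:
        rows.append(
            {
                "dog_id": g.dog_id,
                "breed": g.breed,
                "a88_1": g.pair88[0].format(),
                "a88_2": g.pair88[1].format(),
                "a12_88L_1": g.pair12_88L[0].format(),
                "a12_88L_2": g.pair12_88L[1].format(),
                "drb1_1": g.pairDRB1[0].format(),
                "drb1_2": g.pairDRB1[1].format(),
            }
        )
    _write_tsv(pd.DataFrame(rows, columns=GENOTYPE_COLUMNS), Path(path), meta)


def write_truth(cohort: TrueCohort, path: str | Path, meta: dict | None = None) -> None:
    """Ground-truth diplotypes as dog_id, hap1, hap2 canonical labels."""
    rows = [
        {
            "dog_id": d.dog_id,
            "breed": d.breed,
            "hap1": d.diplotype.hap1.label(),
            "hap2": d.diplotype.hap2.label(),
        }
        for d in cohort.dogs
    ]
    _write_tsv(pd.DataFrame(rows), Path(path), meta)


def read_truth(path: str | Path) -> dict[str, Diplotype]:
    df = _read_tsv(Path(path))
    return {
        r["dog_id"]: Diplotype.of(parse_haplotype(r["hap1"]), parse_haplotype(r["hap2"]))
        for r in df.to_dict("records")
    }


# ---------------------------------------------------------------------
# phasing output


def write_phasing(
    result: PhasingResult,
    phasing_path: str | Path,
    registry_path: str | Path | None = None,
    meta: dict | None = None,
) -> None:
    rows = []
    for r in result.records:
        rows.append(
            {
                "dog_id": r.dog_id,
                "breed": r.breed,
                "status": r.status,
                "tier": r.tier or "NA",
                "hap1": r.diplotype.hap1.label() if r.resolved else "NA",
                "hap2": r.diplotype.hap2.label() if r.resolved else "NA",
                "n_candidates": r.n_candidates,
            }
        )
    _write_tsv(pd.DataFrame(rows), Path(phasing_path), meta)
    if registry_path is not None:
        reg_rows = [
            {
                "haplotype": h.label(),
                "structure": h.structure,
                "first_tier": tier,
            }
            for h, tier in sorted(
                result.registry.items(), key=lambda kv: kv[0].sort_key
            )
        ]
        _write_tsv(pd.DataFrame(reg_rows), Path(registry_path), meta)


def read_phasing(
    phasing_path: str | Path, registry_path: str | Path | None = None
) -> PhasingResult:
    """Rebuild a :class:`PhasingResult` from its TSV output."""
    df = _read_tsv(Path(phasing_path))
    records = []
    for r in df.to_dict("records"):
        resolved = r["status"] == "resolved"
        dip = (
            Diplotype.of(parse_haplotype(r["hap1"]), parse_haplotype(r["hap2"]))
            if resolved
            else None
        )
        records.append(
            DogPhase(
                dog_id=r["dog_id"],
                breed=r["breed"],
                status=r["status"],
                tier=None if r["tier"] == "NA" else r["tier"],
                diplotype=dip,
                n_candidates=int(r["n_candidates"]),
            )
        )
    registry: dict[HaplotypeLabel, str] = {}
    if registry_path is not None:
        reg = _read_tsv(Path(registry_path))
        for r in reg.to_dict("records"):
            registry[parse_haplotype(r["haplotype"])] = r["first_tier"]
    else:
        for rec in records:
            if rec.resolved:
                for h in rec.diplotype.haplotypes:
                    registry.setdefault(h, rec.tier or "unknown")
    return PhasingResult(records=records, registry=registry, n_rounds=0)


# ---------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Pipeline options; all defaults are the documented conventions."""

    seed: int = 0
    n_perm: int = 10000  # HWE Monte-Carlo permutations
    min_count: int = 2  # haplotype-table retention threshold
    rarefaction_g: int | None = None  # default: smallest breed's 2N
    rounding: str = "half_up"  # or "truncate"
    resolve_and_extend: bool = False
    max_rounds: int = 10
    em_tol: float = 1e-8
    min_dogs: int = 10  # per-breed minimum for diversity reports
    denominator: str = "assigned"  # or "all" for coverage percentages
    include_breeds: list[str] | None = None
    exclude_breeds: list[str] | None = None
    pca_drop_breeds: list[str] = field(default_factory=list)
    pca_standardize: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = (
            yaml.safe_load(path.read_text())
            if path.suffix in (".yaml", ".yml")
            else json.loads(path.read_text())
        )
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------
# pipeline


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory handles plus the paths of everything written."""

    config: RunConfig
    genotypes: list[DogGenotype]
    phasing: PhasingResult
    em: object
    table: _div.HaplotypeFrequencyTable
    reports: list[_div.DiversityReport]
    summary: _div.CohortSummary
    coverage: _match.CoverageCurve
    breed_coverage: pd.DataFrame
    spread: pd.DataFrame
    matrix: pd.DataFrame | None
    pca: _struct.PCAResult | None
    paths: dict[str, Path]
    truth: TrueCohort | None = None


def run_pipeline(
    config: RunConfig,
    genotypes: list[DogGenotype] | None = None,
    sim_config: SimConfig | None = None,
    outdir: str | Path = ".",
    prefix: str = "run",
) -> PipelineResult:
    """Execute simulate? -> phase -> tables -> diversity -> matching ->
    structure, writing ``<prefix>.<stage>.tsv`` files under ``outdir``.

    Exactly one of ``genotypes`` / ``sim_config`` must be given.  Every
    output carries the config hash and seed in its header.  Stage errors
    propagate as :class:`PipelineError` naming the stage.
    """
    if (genotypes is None) == (sim_config is None):
        raise ValueError("provide exactly one of genotypes or sim_config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash, "seed": config.seed}
    paths: dict[str, Path] = {}

    def out(stage: str) -> Path:
        p = outdir / f"{prefix}.{stage}.tsv"
        paths[stage] = p
        return p

    truth = None
    try:
        if sim_config is not None:
            truth = simulate_cohort(sim_config)
            genotypes = truth.genotypes()
            write_genotypes(genotypes, out("genotypes"), meta)
            write_truth(truth, out("truth"), meta)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    try:
        result = phase_cohort(
            genotypes,
            max_rounds=config.max_rounds,
            resolve_and_extend=config.resolve_and_extend,
        )
        tiers = result.tier_counts
        logger.info(
            "phased %d/%d dogs (tiers %s; %d unresolved)",
            result.n_resolved,
            len(result.records),
            tiers,
            len(result.records) - result.n_resolved,
        )
        em = em_phase(genotypes, tol=config.em_tol)
        agree = [
            em.modal_diplotypes[r.dog_id] == r.diplotype
            for r in result.resolved_records
        ]
        em_agreement = sum(agree) / len(agree) if agree else math.nan
        logger.info("EM posterior-mode agreement on resolved dogs: %.4f", em_agreement)
        write_phasing(result, out("phasing"), out("registry"), meta)
        em_rows = [
            {"haplotype": h.label(), "em_frequency": f}
            for h, f in sorted(
                em.frequencies.items(), key=lambda kv: -kv[1]
            )
            if f > 1e-12
        ]
        _write_tsv(
            pd.DataFrame(em_rows),
            out("em_frequencies"),
            {**meta, "em_agreement": f"{em_agreement:.4f}"},
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("phase", e) from e

    try:
        table = _div.build_haplotype_table(result, min_count=config.min_count)
        _write_tsv(table.to_frame(), out("haplotypes"), meta)
        _write_tsv(_div.allele_summary(genotypes), out("alleles"), meta)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("tables", e) from e

    try:
        reports = _div.diversity_reports(
            result,
            min_dogs=config.min_dogs,
            g=config.rarefaction_g,
            n_perm=config.n_perm,
            seed=config.seed,
            include=config.include_breeds,
            exclude=config.exclude_breeds,
        )
        summary = _div.cohort_summary(reports)
        _write_tsv(summary.table, out("diversity"), {**meta, "mean_ho": summary.mean_ho})
    except Exception as e:  # noqa: BLE001
        raise PipelineError("diversity", e) from e

    try:
        coverage = _match.coverage_curve(result)
        _write_tsv(coverage.to_frame(), out("coverage"), meta)
        breed_cov = _match.breed_top_coverage(result)
        _write_tsv(breed_cov, out("breed_coverage"), meta)
        spread = _match.breed_spread(table, result)
        _write_tsv(spread, out("breed_spread"), meta)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("matching", e) from e

    matrix = None
    pca_res = None
    try:
        pca_breeds = [
            r.breed for r in reports if not _match._is_mongrel(r.breed)
        ]
        if len(pca_breeds) >= 3:
            matrix = _struct.breed_frequency_matrix(result, breeds=pca_breeds)
            _write_tsv(matrix.reset_index(names="breed"), out("matrix"), meta)
            pca_res = _struct.pca(
                matrix,
                drop_breeds=config.pca_drop_breeds or None,
                standardize=config.pca_standardize,
            )
            _write_tsv(
                pca_res.coordinates.reset_index(names="breed"), out("pca_coords"), meta
            )
            scree = pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(pca_res.n_components)],
                    "eigenvalue": pca_res.eigenvalues,
                    "contribution_ratio": pca_res.contribution_ratios,
                }
            )
            _write_tsv(scree, out("pca_scree"), meta)
        else:
            logger.info("fewer than three eligible breeds: PCA skipped")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("structure", e) from e

    return PipelineResult(
        config=config,
        genotypes=genotypes,
        phasing=result,
        em=em,
        table=table,
        reports=reports,
        summary=summary,
        coverage=coverage,
        breed_coverage=breed_cov,
        spread=spread,
        matrix=matrix,
        pca=pca_res,
        paths=paths,
        truth=truth,
    )
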