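"""Orchestration of a full one-direction or bidirectional MR analysis.

A direction runs: genome-wide significance filter -> LD clumping ->
harmonization -> IVW random effects (principal estimate) -> sensitivity
estimators (weighted median, MR-Egger, MR-PRESSO-corrected, contamination
mixture) -> heterogeneity and pleiotropy diagnostics -> instrument strength
and power. Each stage is logged to standard error; results go only to the
returned report / output files. All randomness flows from the single
configured seed, with fixed per-component offsets so restricting the method
list never changes the surviving stages' outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Sequence

from . import diagnostics, estimators
from .instruments import LDMatrix, instrument_strength, ld_clump, select_by_pvalue
from .power import PowerInput, mr_power_binary
from .summary_data import (
    InstrumentSet,
    VariantAssociation,
    harmonize,
    read_gwas_table,
    write_instrument_set,
)

__all__ = ["MRConfig", "AnalysisReport", "PipelineError", "run_direction", "run_bidirectional"]

log = logging.getLogger("bimr")

_ALL_METHODS = ("ivw", "weighted_median", "egger", "mr_presso", "contamination_mixture")

# Fixed offsets applied to the user seed so every stochastic component has
# an independent, reproducible stream.
_SEED_OFFSETS = {"weighted_median": 1, "mr_presso": 2}


def _version() -> str:
    try:
        return _pkg_version("bimr")
    except PackageNotFoundError:
        return "unknown"


class PipelineError(RuntimeError):
    """Analysis aborted; ``stage`` names the pipeline stage at fault."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class MRConfig:
    """Thresholds, seeds and method selection for one analysis run."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    palindrome_eaf_limit: float = 0.42
    methods: tuple[str, ...] = _ALL_METHODS
    n_boot: int = 1000
    presso_nsim: int = 1000
    presso_alpha: float = 0.05
    conmix_psi: float | str = "auto"
    seed: int = 42
    # Outcome-GWAS case fraction for the power calculation; summary tables
    # do not carry it. None -> 0.5 (most conservative K(1-K)).
    case_fraction_outcome: float | None = None

    def __post_init__(self):
        unknown = set(self.methods) - set(_ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "MRConfig":
        if "methods" in d:
            d = {**d, "methods": tuple(d["methods"])}
        return cls(**d)


@dataclass
class AnalysisReport:
    """All results of one analysis direction plus full provenance."""

    direction: str
    instrument_counts: dict
    estimates: dict                      # method name -> estimate dict (log + OR scale)
    egger_intercept: dict | None
    heterogeneity: dict | None
    presso: dict | None
    strength: dict
    power: dict | None
    provenance: dict
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _load(source, label: str) -> list[VariantAssociation]:
    if isinstance(source, (str, Path)):
        result = read_gwas_table(source)
        if result.rejected:
            log.warning("%s: %d row(s) rejected during read", label, len(result.rejected))
        return result.records
    return list(source)


def run_direction(
    exposure: str | Path | Sequence[VariantAssociation],
    outcome: str | Path | Sequence[VariantAssociation],
    config: MRConfig | None = None,
    ld: LDMatrix | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run one direction of the MR analysis end to end.

    ``exposure``/``outcome`` are file paths or in-memory record collections.
    Aborts with :class:`PipelineError` when fewer than 2 instruments survive
    selection and harmonization.
    """
    cfg = config or MRConfig()
    direction = f"{exposure_name}->{outcome_name}"
    notes: list[str] = []
    t0 = time.perf_counter()

    exp_records = _load(exposure, exposure_name)
    out_records = _load(outcome, outcome_name)
    log.info("%s: read %d exposure / %d outcome records (%.2fs)",
             direction, len(exp_records), len(out_records), time.perf_counter() - t0)

    counts = {"exposure_total": len(exp_records)}
    significant = select_by_pvalue(exp_records, cfg.p_threshold)
    counts["significant"] = len(significant)
    log.info("%s: %d associations at p <= %g", direction, len(significant), cfg.p_threshold)
    if not significant:
        raise PipelineError("select_by_pvalue", "no genome-wide significant associations")

    clumpable = all(
        (ld is not None and ld.index(a.variant_id) is not None)
        or (a.chrom is not None and a.pos is not None)
        for a in significant
    )
    if clumpable:
        independent = ld_clump(significant, ld, cfg.clump_r2, cfg.clump_kb)
        counts["independent"] = len(independent)
        log.info("%s: %d independent instruments after clumping", direction, len(independent))
    else:
        independent = significant
        counts["independent"] = len(independent)
        notes.append("clumping skipped: no LD matrix and no coordinates")
        log.warning("%s: clumping skipped (no LD information)", direction)

    iset = harmonize(
        independent, out_records, cfg.palindrome_eaf_limit,
        exposure_name=exposure_name, outcome_name=outcome_name,
    )
    counts["harmonized"] = len(iset)
    counts["dropped_in_harmonization"] = len(iset.dropped)
    log.info("%s: %d harmonized instruments (%d dropped)",
             direction, len(iset), len(iset.dropped))
    if len(iset) < 2:
        raise PipelineError("harmonize", f"only {len(iset)} instrument(s) survived; need >= 2")
    iset.selection_record.update({
        "p_threshold": cfg.p_threshold,
        "clump_r2": cfg.clump_r2,
        "clump_kb": cfg.clump_kb,
        "counts": dict(counts),
    })

    estimates: dict[str, dict] = {}
    egger_block = None
    presso_block = None
    heterogeneity = None

    principal = estimators.ivw(iset, model="random")
    if "ivw" in cfg.methods:
        estimates["ivw_random"] = principal.to_dict()
        estimates["ivw_fixed"] = estimators.ivw(iset, model="fixed").to_dict()
    heterogeneity = diagnostics.cochran_q(iset, principal.theta).to_dict()

    if "weighted_median" in cfg.methods:
        if len(iset) >= 3:
            wm = estimators.weighted_median(
                iset, n_boot=cfg.n_boot, seed=cfg.seed + _SEED_OFFSETS["weighted_median"]
            )
            estimates["weighted_median"] = wm.to_dict()
        else:
            notes.append("weighted_median skipped: fewer than 3 instruments")

    if "egger" in cfg.methods:
        if len(iset) >= 3:
            eg = estimators.egger(iset)
            estimates["egger"] = eg.slope.to_dict()
            egger_block = {
                "intercept": eg.intercept,
                "se": eg.intercept_se,
                "pvalue": eg.intercept_pvalue,
                "residual_q": eg.residual_q,
            }
        else:
            notes.append("egger skipped: fewer than 3 instruments")

    if "mr_presso" in cfg.methods:
        if len(iset) >= 4:
            pr = diagnostics.mr_presso(
                iset, n_sim=cfg.presso_nsim,
                seed=cfg.seed + _SEED_OFFSETS["mr_presso"],
                outlier_alpha=cfg.presso_alpha,
            )
            presso_block = pr.to_dict()
            if pr.outlier_indices:
                keep = [i for k, i in enumerate(iset.instruments) if k not in pr.outlier_indices]
                estimates["presso_corrected"] = estimators.ivw(keep, model="random").to_dict()
        else:
            notes.append("mr_presso skipped: fewer than 4 instruments")

    if "contamination_mixture" in cfg.methods:
        cm = estimators.contamination_mixture(iset, psi=cfg.conmix_psi)
        d = cm.estimate.to_dict()
        d.update({"psi": cm.psi, "ci_set": [list(iv) for iv in cm.ci_set],
                  "n_valid": int(sum(cm.valid_flags))})
        estimates["contamination_mixture"] = d

    strength = _strength_block(independent)
    power_block = None
    if strength.get("r2_total") is not None:
        n_out = _median_n(out_records)
        k_out = cfg.case_fraction_outcome
        if n_out is not None:
            pinp = PowerInput(
                n=n_out, k_ratio=k_out if k_out is not None else 0.5,
                odds_ratio=float(principal.or_scale[0]) if principal.or_scale[0] != 1 else 1.0 + 1e-9,
                r2=strength["r2_total"],
            )
            power_block = {
                "power": mr_power_binary(pinp),
                "n": pinp.n, "k_ratio": pinp.k_ratio,
                "odds_ratio": pinp.odds_ratio, "r2": pinp.r2, "alpha": pinp.alpha,
                "note": "r2 uses the standardized-trait approximation; case "
                        "fraction defaults to 0.5 when unknown",
            }

    provenance = {
        "exposure_input": str(exposure) if isinstance(exposure, (str, Path)) else "<in-memory>",
        "outcome_input": str(outcome) if isinstance(outcome, (str, Path)) else "<in-memory>",
        "config": {**asdict(cfg), "methods": list(cfg.methods)},
        "selection_record": _jsonable(iset.selection_record),
        "package_version": _version(),
    }
    report = AnalysisReport(
        direction=direction,
        instrument_counts=counts,
        estimates=estimates,
        egger_intercept=egger_block,
        heterogeneity=heterogeneity,
        presso=presso_block,
        strength=_jsonable(strength),
        power=power_block,
        provenance=provenance,
        notes=notes,
    )
    log.info("%s: finished in %.2fs", direction, time.perf_counter() - t0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json())
        _write_estimates_tsv(report, out_dir / "estimates.tsv")
        write_instrument_set(iset, out_dir / "harmonized.tsv")
    return report


def _strength_block(assocs) -> dict:
    n = _median_n(assocs)
    if n is None or n <= len(assocs) + 1:
        return {"per_snp_f": [ (a.beta / a.se) ** 2 for a in assocs],
                "mean_f": float(sum((a.beta / a.se) ** 2 for a in assocs) / len(assocs)),
                "r2_total": None, "aggregate_f": None,
                "note": "sample size unavailable; aggregate F not computed"}
    s = instrument_strength(assocs, n)
    return {"per_snp_f": list(s.per_snp_f), "mean_f": s.mean_f,
            "r2_total": s.r2_total, "aggregate_f": s.aggregate_f, "n": n}


def _median_n(records) -> int | None:
    ns = sorted(r.n for r in records if getattr(r, "n", None) is not None)
    return ns[len(ns) // 2] if ns else None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def _write_estimates_tsv(report: AnalysisReport, path: Path) -> None:
    cols = ["method", "theta", "se", "ci_low", "ci_high", "pvalue",
            "odds_ratio", "or_ci_low", "or_ci_high", "n_snps"]
    lines = ["\t".join(cols)]
    for name, est in report.estimates.items():
        lines.append("\t".join(
            repr(est.get(c)) if isinstance(est.get(c), float) else str(est.get(c))
            for c in cols
        ))
    path.write_text("\n".join(lines) + "\n")


def run_bidirectional(
    a: str | Path | Sequence[VariantAssociation],
    b: str | Path | Sequence[VariantAssociation],
    config: MRConfig | None = None,
    ld_a: LDMatrix | None = None,
    ld_b: LDMatrix | None = None,
    a_name: str = "trait_a",
    b_name: str = "trait_b",
    out_dir: str | Path | None = None,
) -> dict:
    """Run both analysis directions; one may fail while the other completes.

    Returns ``{"forward": report-or-error, "reverse": report-or-error,
    "sample_overlap_flag": bool}``; the overlap flag marks identical input
    files (complete sample overlap).
    """
    cfg = config or MRConfig()
    overlap = (
        isinstance(a, (str, Path)) and isinstance(b, (str, Path))
        and Path(a).resolve() == Path(b).resolve()
    )
    result: dict = {"sample_overlap_flag": overlap}
    for key, (exp, out, ld, en, on) in {
        "forward": (a, b, ld_a, a_name, b_name),
        "reverse": (b, a, ld_b, b_name, a_name),
    }.items():
        sub = Path(out_dir) / key if out_dir is not None else None
        try:
            result[key] = run_direction(exp, out, cfg, ld, en, on, out_dir=sub)
        except (PipelineError, ValueError) as exc:
            log.error("%s direction failed: %s", key, exc)
            result[key] = {"error": str(exc), "stage": getattr(exc, "stage", "unknown")}
    if out_dir is not None:
        summary = {
            k: (v.to_dict() if isinstance(v, AnalysisReport) else v) for k, v in result.items()
        }
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "bidirectional.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return result
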