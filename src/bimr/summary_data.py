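"""Reading, validation and harmonization of GWAS summary statistics.

A two-sample Mendelian randomization analysis combines per-variant effect
estimates from an exposure GWAS and an outcome GWAS. Before any causal
estimator can run, the two tables must be aligned so that every effect is
expressed per copy of the *same* effect allele. This module reads
tab-separated summary tables into :class:`VariantAssociation` records,
harmonizes exposure/outcome pairs into :class:`HarmonizedInstrument` objects
(resolving allele swaps, strand flips and palindromic ambiguity), and
computes the per-variant Wald ratio — the outcome effect divided by the
exposure effect — which is the raw material of every downstream estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "VariantAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "RowIssue",
    "ReadResult",
    "DEFAULT_DIALECT",
    "read_gwas_table",
    "write_gwas_table",
    "harmonize",
    "write_instrument_set",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GwasInputError(ValueError):
    """Raised for unusable input files or configuration."""


@dataclass(frozen=True, slots=True)
class VariantAssociation:
    """One variant's association with one trait, on the log-odds scale.

    ``beta`` is the additive effect per copy of ``effect_allele``; ``eaf``
    is the effect-allele frequency (``None`` when the source GWAS did not
    report it). ``chrom``/``pos`` are only needed for distance-based
    clumping.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not 0 < self.pvalue <= 1:
            raise ValueError(f"{self.variant_id}: pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.variant_id}: eaf must be in (0,1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variants, whose strand cannot be read off the alleles."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True, slots=True)
class HarmonizedInstrument:
    """A variant with aligned exposure and outcome effects plus its Wald ratio."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    wald_ratio: float
    wald_se: float
    harmonization_action: str  # unchanged | allele_flipped | palindromic_aligned | dropped
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None


@dataclass(slots=True)
class InstrumentSet:
    """An ordered, harmonized set of instruments for one analysis direction."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    dropped: list[HarmonizedInstrument] = field(default_factory=list)
    selection_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [i.variant_id for i in self.instruments]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant_id in instrument set")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)


class RowIssue(NamedTuple):
    row: int
    variant_id: str
    field: str
    message: str


class ReadResult(NamedTuple):
    records: list[VariantAssociation]
    rejected: list[RowIssue]


#: Column names expected in input tables unless a custom mapping is given.
DEFAULT_DIALECT: Mapping[str, str] = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "n": "n",
    "chrom": "chrom",
    "pos": "pos",
}

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
_OPTIONAL = ("eaf", "n", "chrom", "pos")


def read_gwas_table(path: str | Path, dialect: Mapping[str, str] | None = None) -> ReadResult:
    """Read a tab-separated GWAS summary table.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the column names used in the file. Rows violating the record
    invariants are rejected individually and reported in
    ``ReadResult.rejected``; a missing mandatory column or an empty file is a
    :class:`GwasInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise GwasInputError(f"no such file: {path}")
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise GwasInputError(f"{path}: table has no data rows")
    missing = [mapping[f] for f in _MANDATORY if mapping[f] not in df.columns]
    if missing:
        raise GwasInputError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[VariantAssociation] = []
    rejected: list[RowIssue] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        raw = dict(zip(df.columns, row))
        vid = str(raw.get(mapping["variant_id"], "")).strip()
        try:
            kwargs: dict = {
                "variant_id": vid,
                "effect_allele": str(raw[mapping["effect_allele"]]).strip().upper(),
                "other_allele": str(raw[mapping["other_allele"]]).strip().upper(),
            }
            for fld, caster in (("beta", float), ("se", float), ("pvalue", float)):
                try:
                    kwargs[fld] = caster(raw[mapping[fld]])
                except (TypeError, ValueError):
                    raise _FieldError(fld, f"unparseable value {raw[mapping[fld]]!r}")
            for fld, caster in (("eaf", float), ("n", _as_int), ("pos", _as_int)):
                col = mapping[fld]
                if col in df.columns and not _is_missing(raw.get(col)):
                    try:
                        kwargs[fld] = caster(raw[col])
                    except (TypeError, ValueError):
                        raise _FieldError(fld, f"unparseable value {raw[col]!r}")
            col = mapping["chrom"]
            if col in df.columns and not _is_missing(raw.get(col)):
                kwargs["chrom"] = str(raw[col]).strip()
            records.append(VariantAssociation(**kwargs))
        except _FieldError as exc:
            rejected.append(RowIssue(idx, vid, exc.field, exc.message))
        except ValueError as exc:
            fld = _invariant_field(str(exc))
            rejected.append(RowIssue(idx, vid, fld, str(exc)))
    return ReadResult(records, rejected)


class _FieldError(Exception):
    def __init__(self, field: str, message: str):
        self.field = field
        self.message = message
        super().__init__(message)


def _invariant_field(msg: str) -> str:
    for fld in ("effect allele", "other allele", "se", "pvalue", "eaf", "allele"):
        if fld in msg:
            return fld.replace(" ", "_")
    return "record"


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() in ("", "NA", "nan", "NaN", ".")


def _as_int(v) -> int:
    f = float(v)
    if f != int(f):
        raise ValueError(f"not an integer: {v}")
    return int(f)


def write_gwas_table(records: Iterable[VariantAssociation], path: str | Path) -> None:
    """Write records as a TSV in the default dialect, full float precision."""
    rows = []
    for r in records:
        rows.append({
            "variant_id": r.variant_id,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": repr(r.eaf) if r.eaf is not None else "NA",
            "beta": repr(r.beta),
            "se": repr(r.se),
            "pvalue": repr(r.pvalue),
            "n": r.n if r.n is not None else "NA",
            "chrom": r.chrom if r.chrom is not None else "NA",
            "pos": r.pos if r.pos is not None else "NA",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_eaf_limit: float = 0.42,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    For each variant present in both collections:

    * identical allele pair — kept as-is;
    * swapped alleles — outcome beta negated, eaf complemented;
    * complementary-strand pair (direct or swapped) — strand-flipped first,
      then the same rules;
    * palindromic (A/T, C/G) — retained only when both allele frequencies
      are informative: outside ``[limit, 1-limit]`` and on the same side of
      0.5 after textual alignment; otherwise dropped;
    * irreconcilable allele pairs and zero exposure betas — dropped, with
      the action recorded.

    The Wald ratio ``beta_outcome / beta_exposure`` and its first-order
    standard error ``se_outcome / |beta_exposure|`` are attached to every
    retained instrument.
    """
    if not 0 < palindrome_eaf_limit < 0.5:
        raise ValueError("palindrome_eaf_limit must be in (0, 0.5)")
    outcome_by_id = {o.variant_id: o for o in outcome}

    kept: list[HarmonizedInstrument] = []
    dropped: list[HarmonizedInstrument] = []
    n_shared = 0
    for exp in exposure:
        out = outcome_by_id.get(exp.variant_id)
        if out is None:
            continue
        n_shared += 1
        inst = _harmonize_one(exp, out, palindrome_eaf_limit)
        (dropped if inst.harmonization_action == "dropped" else kept).append(inst)

    return InstrumentSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        instruments=kept,
        dropped=dropped,
        selection_record={
            "palindrome_eaf_limit": palindrome_eaf_limit,
            "n_exposure": len(exposure),
            "n_outcome": len(outcome),
            "n_shared": n_shared,
            "n_retained": len(kept),
            "n_dropped": len(dropped),
        },
    )


def _harmonize_one(
    exp: VariantAssociation, out: VariantAssociation, limit: float
) -> HarmonizedInstrument:
    ea, oa = exp.effect_allele, exp.other_allele

    def make(beta_out: float, eaf_out: float | None, action: str) -> HarmonizedInstrument:
        if action != "dropped" and exp.beta == 0:
            return make(beta_out, eaf_out, "dropped")
        if action == "dropped":
            return HarmonizedInstrument(
                variant_id=exp.variant_id,
                beta_exposure=exp.beta, se_exposure=exp.se,
                beta_outcome=beta_out, se_outcome=out.se,
                wald_ratio=float("nan"), wald_se=float("nan"),
                harmonization_action="dropped",
                eaf_exposure=exp.eaf, eaf_outcome=eaf_out,
            )
        return HarmonizedInstrument(
            variant_id=exp.variant_id,
            beta_exposure=exp.beta, se_exposure=exp.se,
            beta_outcome=beta_out, se_outcome=out.se,
            wald_ratio=beta_out / exp.beta,
            wald_se=out.se / abs(exp.beta),
            harmonization_action=action,
            eaf_exposure=exp.eaf, eaf_outcome=eaf_out,
        )

    if exp.is_palindromic:
        # Textual alignment first; ambiguity then resolved by allele frequency.
        if (out.effect_allele, out.other_allele) == (ea, oa):
            beta_o, eaf_o = out.beta, out.eaf
        elif (out.effect_allele, out.other_allele) == (oa, ea):
            beta_o = -out.beta
            eaf_o = None if out.eaf is None else 1 - out.eaf
        else:
            return make(out.beta, out.eaf, "dropped")
        if exp.eaf is None or eaf_o is None:
            return make(beta_o, eaf_o, "dropped")
        informative = (
            not (limit <= exp.eaf <= 1 - limit)
            and not (limit <= eaf_o <= 1 - limit)
            and (exp.eaf - 0.5) * (eaf_o - 0.5) > 0
        )
        if not informative:
            return make(beta_o, eaf_o, "dropped")
        return make(beta_o, eaf_o, "palindromic_aligned")

    o_ea, o_oa = out.effect_allele, out.other_allele
    if (o_ea, o_oa) == (ea, oa):
        return make(out.beta, out.eaf, "unchanged")
    if (o_ea, o_oa) == (oa, ea):
        return make(-out.beta, None if out.eaf is None else 1 - out.eaf, "allele_flipped")
    c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (ea, oa):
        return make(out.beta, out.eaf, "allele_flipped")
    if (c_ea, c_oa) == (oa, ea):
        return make(-out.beta, None if out.eaf is None else 1 - out.eaf, "allele_flipped")
    return make(out.beta, out.eaf, "dropped")


def write_instrument_set(iset: InstrumentSet, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Serialize a harmonized set as TSV plus a JSON sidecar of the selection record."""
    tsv_path = Path(tsv_path)
    rows = []
    for i in iset.instruments + iset.dropped:
        rows.append({
            "variant_id": i.variant_id,
            "beta_exposure": repr(i.beta_exposure),
            "se_exposure": repr(i.se_exposure),
            "beta_outcome": repr(i.beta_outcome),
            "se_outcome": repr(i.se_outcome),
            "wald_ratio": repr(i.wald_ratio),
            "wald_se": repr(i.wald_se),
            "harmonization_action": i.harmonization_action,
        })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    sidecar = Path(sidecar_path) if sidecar_path else tsv_path.with_suffix(".json")
    record = dict(iset.selection_record)
    record.update({"exposure_name": iset.exposure_name, "outcome_name": iset.outcome_name})
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
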