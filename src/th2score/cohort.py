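"""Cohort domain types, CSV I/O and descriptive summaries.

A cohort is an ordered collection of participants, each carrying a confirmed
diagnosis label (the reference standard), the four-marker inflammation panel
(FENO in ppb, total IgE in IU/mL, blood eosinophil count in cells/uL, skin
prick positivity) and optional covariates (sex, weight, baseline FEV1 %pred).
Units are taken as given; no conversion is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, RowParseError, SchemaError
from .render import fmt_pct

logger = logging.getLogger(__name__)

__all__ = [
    "Participant",
    "Cohort",
    "GroupSummary",
    "DEFAULT_SCHEMA",
    "read_cohort",
    "write_cohort",
    "summarize_group",
    "cohort_counts",
]

#: Default CSV column names; remap via the ``schema`` argument of
#: :func:`read_cohort` when your file uses different headers.
DEFAULT_SCHEMA: dict[str, str] = {
    "id": "id",
    "asthma": "asthma",
    "feno": "feno",
    "ige": "ige",
    "bec": "bec",
    "prick": "prick",
    "sex": "sex",
    "weight": "weight",
    "fev1_pct": "fev1_pct",
}

_REQUIRED = ("id", "asthma", "feno", "ige", "bec", "prick")
_OPTIONAL = ("sex", "weight", "fev1_pct")

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class Participant:
    """One athlete: diagnosis label, biomarker panel, optional covariates."""

    id: str
    asthma: bool
    feno: float
    ige: float
    bec: float
    prick_positive: bool
    sex: Literal["male", "female"] | None = None
    weight: float | None = None
    fev1_pct: float | None = None

    def __post_init__(self) -> None:
        for name in ("feno", "ige", "bec"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative real, got {v!r}")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("weight", "fev1_pct"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be a positive real, got {v!r}")


@dataclass
class Cohort:
    """Ordered collection of participants with a provenance label."""

    participants: list[Participant]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate participant ids: {dup}")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[Participant]:
        return iter(self.participants)

    def values(self, marker: str) -> np.ndarray:
        """Numeric vector of one attribute across the cohort."""
        return np.array([getattr(p, marker) for p in self.participants], dtype=float)

    def labels(self) -> np.ndarray:
        """Boolean diagnosis vector (True = asthma)."""
        return np.array([p.asthma for p in self.participants], dtype=bool)

    def split(self) -> tuple["Cohort", "Cohort"]:
        """(no-asthma cohort, asthma cohort) preserving order."""
        neg = [p for p in self.participants if not p.asthma]
        pos = [p for p in self.participants if p.asthma]
        return (
            Cohort(neg, provenance=f"{self.provenance}/no_asthma"),
            Cohort(pos, provenance=f"{self.provenance}/asthma"),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "id": p.id,
                    "asthma": int(p.asthma),
                    "feno": p.feno,
                    "ige": p.ige,
                    "bec": p.bec,
                    "prick": int(p.prick_positive),
                    "sex": "" if p.sex is None else p.sex,
                    "weight": "" if p.weight is None else p.weight,
                    "fev1_pct": "" if p.fev1_pct is None else p.fev1_pct,
                }
            )
        return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))


@dataclass(frozen=True)
class GroupSummary:
    """n, mean, sample SD and quartiles of one variable in one group."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartile ordering violated")

    def render_mean_sd(self, decimals: int = 1) -> str:
        return f"{self.mean:.{decimals}f} ± {self.sd:.{decimals}f}"

    def render_median_iqr(self, decimals: int = 1) -> str:
        return (
            f"{self.median:.{decimals}f} "
            f"({self.q1:.{decimals}f}–{self.q3:.{decimals}f})"
        )


def _parse_bool(raw: object, column: str, row: int) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    if isinstance(raw, (int, np.integer)) and raw in (0, 1):
        return bool(raw)
    if isinstance(raw, (float, np.floating)) and raw in (0.0, 1.0):
        return bool(raw)
    s = str(raw).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise RowParseError(
        f"row {row}: cannot parse {column}={raw!r} as a boolean", row=row
    )


def _parse_sex(raw: object, row: int) -> Literal["male", "female"] | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip().lower()
    if s in ("", "na", "nan", "none"):
        return None
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    raise RowParseError(f"row {row}: cannot parse sex={raw!r}", row=row)


def _parse_optional_float(raw: object, column: str, row: int) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, (float, np.floating)) and math.isnan(raw):
        return None
    s = str(raw).strip()
    if s.lower() in ("", "na", "nan", "none"):
        return None
    try:
        return float(s)
    except ValueError:
        raise RowParseError(
            f"row {row}: cannot parse {column}={raw!r} as a number", row=row
        ) from None


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
    provenance: str | None = None,
) -> Cohort:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path:
        CSV file with a header row (RFC 4180, UTF-8).
    schema:
        Mapping from canonical field names (``id, asthma, feno, ige, bec,
        prick, sex, weight, fev1_pct``) to the file's column names. Missing
        optional fields are tolerated; missing required fields raise
        :class:`~th2score.errors.SchemaError`.
    strict:
        If True (default), a row with a missing/unparseable required value
        raises :class:`~th2score.errors.RowParseError`. If False, such rows
        are dropped with a logged count.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
        colmap.update(schema)

    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None

    for field_name in _REQUIRED:
        if colmap[field_name] not in frame.columns:
            raise SchemaError(
                f"required column {colmap[field_name]!r} (field {field_name!r}) "
                f"not found in {path}"
            )
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: header only, no data rows")

    have_optional = {f: colmap[f] in frame.columns for f in _OPTIONAL}

    participants: list[Participant] = []
    dropped = 0
    for i, rec in enumerate(frame.to_dict("records")):
        try:
            feno = _parse_optional_float(rec[colmap["feno"]], "feno", i)
            ige = _parse_optional_float(rec[colmap["ige"]], "ige", i)
            bec = _parse_optional_float(rec[colmap["bec"]], "bec", i)
            if feno is None or ige is None or bec is None:
                missing = [
                    n for n, v in (("feno", feno), ("ige", ige), ("bec", bec))
                    if v is None
                ]
                raise RowParseError(
                    f"row {i}: missing required biomarker(s) {missing}", row=i
                )
            p = Participant(
                id=str(rec[colmap["id"]]).strip(),
                asthma=_parse_bool(rec[colmap["asthma"]], "asthma", i),
                feno=feno,
                ige=ige,
                bec=bec,
                prick_positive=_parse_bool(rec[colmap["prick"]], "prick", i),
                sex=_parse_sex(rec[colmap["sex"]], i) if have_optional["sex"] else None,
                weight=_parse_optional_float(rec[colmap["weight"]], "weight", i)
                if have_optional["weight"]
                else None,
                fev1_pct=_parse_optional_float(rec[colmap["fev1_pct"]], "fev1_pct", i)
                if have_optional["fev1_pct"]
                else None,
            )
        except (RowParseError, ValueError) as exc:
            if strict:
                if isinstance(exc, RowParseError):
                    raise
                raise RowParseError(f"row {i}: {exc}", row=i) from exc
            dropped += 1
            logger.warning("dropping row %d: %s", i, exc)
            continue
        participants.append(p)

    if dropped:
        logger.warning("read_cohort: dropped %d row(s) with invalid data", dropped)
    if not participants:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    return Cohort(participants, provenance=provenance or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to CSV in the default schema."""
    cohort.to_frame().to_csv(path, index=False)


def summarize_group(
    values: Iterable[float] | Sequence[float] | np.ndarray,
    quartile_method: str = "linear",
) -> GroupSummary:
    """Descriptive summary: mean, sample SD (n-1), median and quartiles.

    Quartiles use linear interpolation between order statistics by default
    (numpy's ``linear`` method, R type 7); other numpy quantile methods may
    be passed through ``quartile_method``.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if x.size == 0:
        raise EmptyInputError("summarize_group: empty input")
    sd = 0.0 if x.size == 1 else float(np.std(x, ddof=1))
    q1, med, q3 = (
        float(np.quantile(x, q, method=quartile_method)) for q in (0.25, 0.5, 0.75)
    )
    return GroupSummary(
        n=int(x.size), mean=float(np.mean(x)), sd=sd, median=med, q1=q1, q3=q3
    )


def cohort_counts(cohort: Cohort) -> dict:
    """Diagnosis counts and prevalence (fraction, plus integer-% rendering)."""
    if len(cohort) == 0:
        raise EmptyInputError("cohort_counts: empty cohort")
    n_pos = int(sum(p.asthma for p in cohort))
    n_total = len(cohort)
    prevalence = n_pos / n_total
    return {
        "n_total": n_total,
        "n_pos": n_pos,
        "n_neg": n_total - n_pos,
        "prevalence": prevalence,
        "prevalence_pct": fmt_pct(prevalence, decimals=0),
    }
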