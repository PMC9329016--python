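"""Reading, validation and phenotype stratification of binary comorbidity cohorts.

A cohort is one row per patient: an opaque subject id, two binary phenotype
flags (chronic bronchitis CB+/CB-, prior severe exacerbation Ex+/Ex-) and one
binary column per candidate disease.  Missing disease cells are first-class:
per-disease denominators exclude them (pairwise deletion downstream), they are
never imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: tokens accepted in a disease cell (after stripping); everything else errors
_MISSING_TOKENS = {"", "na", "nan", "none", "null"}
_PRESENT_TOKENS = {"1"}
_ABSENT_TOKENS = {"0"}


class CohortError(ValueError):
    """Malformed cohort file or invalid cell/flag content."""


@dataclass
class CohortTable:
    """Binary subjects x diseases matrix with phenotype flags.

    Parameters
    ----------
    subject_id : sequence of str
        Unique opaque identifiers, one per row.
    cb, ex : ndarray of float
        Phenotype flags in {0.0, 1.0, nan}; nan means the flag was not
        recorded (rejected later by :func:`split_by_phenotype`).
    diseases : DataFrame of float
        One column per disease, values in {0.0, 1.0, nan}; nan is missing.
    """

    subject_id: np.ndarray
    cb: np.ndarray
    ex: np.ndarray
    diseases: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.cb = np.asarray(self.cb, dtype=float)
        self.ex = np.asarray(self.ex, dtype=float)
        n = len(self.subject_id)
        if n < 1:
            raise CohortError("cohort must contain at least one subject")
        if len(set(self.subject_id)) != n:
            raise CohortError("subject_id values are not unique")
        if self.cb.shape != (n,) or self.ex.shape != (n,):
            raise CohortError("phenotype flag length does not match subjects")
        if len(self.diseases) != n:
            raise CohortError("disease matrix length does not match subjects")
        names = list(self.diseases.columns)
        if len(set(names)) != len(names) or any(not str(d) for d in names):
            raise CohortError("disease names must be unique and non-empty")
        vals = self.diseases.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise CohortError(
                f"non-binary value {vals[r, c]!r} in disease column "
                f"{names[c]!r}, subject {self.subject_id[r]!r}"
            )
        for flag, lbl in ((self.cb, "cb"), (self.ex, "ex")):
            bad = ~(np.isnan(flag) | (flag == 0.0) | (flag == 1.0))
            if bad.any():
                i = int(np.argmax(bad))
                raise CohortError(
                    f"non-binary {lbl} flag for subject {self.subject_id[i]!r}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    @property
    def disease_names(self) -> list[str]:
        return list(self.diseases.columns)

    def take(self, rows: np.ndarray) -> "CohortTable":
        """Row subset preserving order; used by stratification and bootstrap."""
        return CohortTable(
            subject_id=self.subject_id[rows],
            cb=self.cb[rows],
            ex=self.ex[rows],
            diseases=self.diseases.iloc[rows].reset_index(drop=True),
        )


@dataclass
class ValidationReport:
    n_subjects: int
    per_disease_denominator: dict[str, int]
    per_disease_prevalence: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "n_subjects": self.n_subjects,
                "per_disease_denominator": self.per_disease_denominator,
                "per_disease_prevalence": self.per_disease_prevalence,
                "warnings": self.warnings,
            },
            sort_keys=True,
            **kwargs,
        )


class PhenotypeSplit(NamedTuple):
    positive: CohortTable | None
    negative: CohortTable | None


def _parse_cell(token: str) -> float:
    t = token.strip().lower()
    if t in _PRESENT_TOKENS:
        return 1.0
    if t in _ABSENT_TOKENS:
        return 0.0
    if t in _MISSING_TOKENS:
        return np.nan
    raise ValueError(token)


def load_column_config(path) -> dict:
    """Read a YAML/JSON column-mapping config.

    Required keys: ``subject``, ``cb``, ``ex``, ``diseases`` (list).  Optional:
    ``delimiter`` (default inferred from extension: ``.tsv`` -> tab, else
    comma).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    missing = {"subject", "cb", "ex", "diseases"} - set(cfg)
    if missing:
        raise CohortError(f"column config missing keys: {sorted(missing)}")
    return cfg


def read_cohort(path, config: Mapping) -> CohortTable:
    """Read a delimited cohort file using an explicit column mapping.

    Columns are bound by the config, never inferred from headers, so a renamed
    or reordered file cannot silently swap phenotype flags.  Disease cells
    accept only {0, 1, empty/NA}; any other token raises naming the column and
    subject.  Missing cells are preserved as missing.
    """
    disease_cols = list(config["diseases"])
    if len(disease_cols) < 2:
        raise CohortError("config must name at least 2 disease columns")
    delim = config.get("delimiter")
    if delim is None:
        delim = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        raw = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise CohortError(f"malformed cohort file {path}: {exc}") from exc
    for col in [config["subject"], config["cb"], config["ex"], *disease_cols]:
        if col not in raw.columns:
            raise CohortError(f"column {col!r} not found in {path}")

    subject = raw[config["subject"]].to_numpy(dtype=object)
    flags = {}
    for key in ("cb", "ex"):
        parsed = np.empty(len(raw), dtype=float)
        for i, tok in enumerate(raw[config[key]]):
            try:
                parsed[i] = _parse_cell(tok)
            except ValueError:
                raise CohortError(
                    f"non-binary value {tok!r} in phenotype column "
                    f"{config[key]!r}, row {i + 2}"
                ) from None
        flags[key] = parsed

    mat = np.empty((len(raw), len(disease_cols)), dtype=float)
    for c, col in enumerate(disease_cols):
        for i, tok in enumerate(raw[col]):
            try:
                mat[i, c] = _parse_cell(tok)
            except ValueError:
                raise CohortError(
                    f"non-binary value {tok!r} in disease column {col!r}, "
                    f"row {i + 2} (subject {subject[i]!r})"
                ) from None
    diseases = pd.DataFrame(mat, columns=disease_cols)
    return CohortTable(subject, flags["cb"], flags["ex"], diseases)


def write_cohort(cohort: CohortTable, path, *, delimiter: str = ",") -> None:
    """Write a cohort in the dialect :func:`read_cohort` accepts (round-trip safe)."""
    out = pd.DataFrame({"subject_id": cohort.subject_id})
    fmt = lambda v: "" if np.isnan(v) else str(int(v))  # noqa: E731
    out["cb"] = [fmt(v) for v in cohort.cb]
    out["ex"] = [fmt(v) for v in cohort.ex]
    for d in cohort.disease_names:
        out[d] = [fmt(v) for v in cohort.diseases[d].to_numpy()]
    out.to_csv(path, sep=delimiter, index=False)


def default_column_config(cohort: CohortTable) -> dict:
    """Column mapping matching :func:`write_cohort` output."""
    return {
        "subject": "subject_id",
        "cb": "cb",
        "ex": "ex",
        "diseases": cohort.disease_names,
    }


def validate_cohort(cohort: CohortTable) -> ValidationReport:
    """Per-disease denominators and prevalences over non-missing cells only.

    A disease measured in fewer subjects than the cohort size gets the reduced
    denominator; warnings flag degenerate (all-present / all-absent) columns
    and unrecorded phenotype flags.
    """
    vals = cohort.diseases.to_numpy(dtype=float)
    present = np.nansum(vals, axis=0).astype(int)
    denom = (~np.isnan(vals)).sum(axis=0).astype(int)
    warnings: list[str] = []
    denominators: dict[str, int] = {}
    prevalences: dict[str, float] = {}
    for k, name in enumerate(cohort.disease_names):
        denominators[name] = int(denom[k])
        if denom[k] == 0:
            prevalences[name] = float("nan")
            warnings.append(f"disease {name!r}: no non-missing observations")
            continue
        p = present[k] / denom[k]
        prevalences[name] = float(p)
        if p in (0.0, 1.0):
            warnings.append(f"disease {name!r}: degenerate prevalence {p:g}")
    for flag, lbl in ((cohort.cb, "cb"), (cohort.ex, "ex")):
        n_miss = int(np.isnan(flag).sum())
        if n_miss:
            warnings.append(f"{n_miss} subjects lack the {lbl} phenotype flag")
    for w in warnings:
        logger.warning("%s", w)
    return ValidationReport(cohort.n_subjects, denominators, prevalences, warnings)


def split_by_phenotype(cohort: CohortTable, trait: str) -> PhenotypeSplit:
    """Partition a cohort into (trait-positive, trait-negative) tables.

    ``trait`` is ``"cb"`` or ``"ex"``.  Every subject must carry the flag;
    a missing flag raises naming the subject.  An empty side is returned as
    ``None`` with a logged warning rather than a zero-row table (CohortTable
    requires at least one row).
    """
    trait = trait.lower()
    if trait not in ("cb", "ex"):
        raise ValueError(f"trait must be 'cb' or 'ex', got {trait!r}")
    flag = cohort.cb if trait == "cb" else cohort.ex
    nanmask = np.isnan(flag)
    if nanmask.any():
        subj = cohort.subject_id[int(np.argmax(nanmask))]
        raise CohortError(f"subject {subj!r} lacks the {trait} phenotype flag")
    pos_rows = np.flatnonzero(flag == 1.0)
    neg_rows = np.flatnonzero(flag == 0.0)
    pos = cohort.take(pos_rows) if len(pos_rows) else None
    neg = cohort.take(neg_rows) if len(neg_rows) else None
    if pos is None or neg is None:
        logger.warning("split_by_phenotype(%s): one stratum is empty", trait)
    return PhenotypeSplit(positive=pos, negative=neg)
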