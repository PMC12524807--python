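"""Loading, alignment and standardization of expression/clinical tables.

File contracts
--------------
Expression: TSV, one row per sample, first column ``sample_id``, remaining
header entries are gene symbols, continuous values, UTF-8.
Clinical: TSV with exactly the columns ``sample_id``, ``time`` (days, > 0)
and ``event`` (0 censored / 1 death observed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSignature",
    "SurvivalCohort",
    "Standardizer",
    "AlignmentReport",
    "CohortFormatError",
    "CohortValidationError",
    "load_cohort",
    "save_cohort",
    "align_to_signature",
    "fit_standardizer",
    "apply_standardizer",
]


class CohortFormatError(ValueError):
    """Input file does not match the expected table layout."""


class CohortValidationError(ValueError):
    """Loaded values violate a cohort invariant."""


def _norm_gene(g: str) -> str:
    return str(g).strip().upper()


@dataclass(frozen=True)
class GeneSignature:
    """An ordered list of gene symbols defining the model's feature space."""

    genes: tuple[str, ...]

    def __post_init__(self):
        normed = [_norm_gene(g) for g in self.genes]
        if not normed:
            raise CohortValidationError("gene signature is empty")
        if len(set(normed)) != len(normed):
            raise CohortValidationError("gene signature contains duplicate symbols")
        object.__setattr__(self, "genes", tuple(normed))

    def __len__(self):
        return len(self.genes)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneSignature":
        """Read one gene symbol per line; blank lines ignored."""
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls(tuple(ln for ln in lines if ln))


@dataclass
class SurvivalCohort:
    """Expression matrix plus right-censored survival labels.

    ``X`` is samples x genes; ``time`` in days (> 0); ``event`` is 1 when the
    death was observed and 0 when the subject was censored.
    """

    sample_ids: list[str]
    genes: list[str]
    X: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.time = np.asarray(self.time, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        self.validate()

    def validate(self):
        n, g = self.X.shape
        if len(self.sample_ids) != n or len(self.time) != n or len(self.event) != n:
            raise CohortValidationError("row counts of X, sample_ids, time, event differ")
        if len(self.genes) != g:
            raise CohortValidationError("gene list length does not match X columns")
        if len(set(self.sample_ids)) != n:
            raise CohortValidationError("sample ids are not unique")
        if np.isnan(self.X).any():
            raise CohortValidationError("expression matrix contains missing values")
        bad_t = np.where(~(self.time > 0))[0]
        if bad_t.size:
            raise CohortValidationError(
                f"non-positive survival time for sample {self.sample_ids[bad_t[0]]!r}"
            )
        bad_e = np.where(~np.isin(self.event, (0, 1)))[0]
        if bad_e.size:
            raise CohortValidationError(
                f"event indicator outside {{0,1}} for sample {self.sample_ids[bad_e[0]]!r}"
            )
        if self.event.sum() < 1:
            raise CohortValidationError("cohort has no observed events")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset(self, rows) -> "SurvivalCohort":
        rows = np.asarray(rows)
        return SurvivalCohort(
            [self.sample_ids[i] for i in rows],
            list(self.genes),
            self.X[rows],
            self.time[rows],
            self.event[rows],
        )


@dataclass
class AlignmentReport:
    """Which signature genes a cohort actually carries."""

    present: list[str]
    absent: list[str]

    @property
    def retention(self) -> float:
        total = len(self.present) + len(self.absent)
        return len(self.present) / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, 1) for g in self.present] + [(g, 0) for g in self.absent]
        return pd.DataFrame(rows, columns=["gene", "present"])


@dataclass
class Standardizer:
    """Per-gene location/scale fitted on training rows only.

    Genes constant in the training rows get scale 1 so their transformed
    values are exactly 0 rather than NaN.
    """

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=np.float64) * self.scale + self.mean


def load_cohort(expression_path: str | Path, clinical_path: str | Path) -> SurvivalCohort:
    """Load and inner-join expression and clinical TSVs.

    Samples present in both files are kept, in the expression file's order.
    """
    with open(expression_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2 or header[0] != "sample_id":
        raise CohortFormatError(
            f"{expression_path}: first column must be 'sample_id' followed by genes"
        )
    raw_genes = [_norm_gene(g) for g in header[1:]]
    seen: set[str] = set()
    usecols, genes = [0], []
    for i, g in enumerate(raw_genes):
        if g in seen:
            continue
        seen.add(g)
        usecols.append(i + 1)
        genes.append(g)
    if len(genes) != len(raw_genes):
        warnings.warn(
            f"dropping {len(raw_genes) - len(genes)} duplicate gene column(s), "
            "keeping first occurrence", stacklevel=2,
        )
    expr = pd.read_csv(expression_path, sep="\t", dtype={0: str},
                       usecols=usecols, float_precision="round_trip")
    clin = pd.read_csv(clinical_path, sep="\t", dtype={"sample_id": str},
                       float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    if not required.issubset(clin.columns):
        raise CohortFormatError(
            f"{clinical_path}: missing columns {sorted(required - set(clin.columns))}"
        )
    clin = clin.set_index("sample_id")
    keep = [s for s in expr["sample_id"] if s in clin.index]
    if not keep:
        raise CohortFormatError("no samples shared between expression and clinical tables")
    expr = expr.set_index("sample_id").loc[keep]
    clin = clin.loc[keep]

    return SurvivalCohort(
        sample_ids=list(expr.index),
        genes=genes,
        X=expr.to_numpy(dtype=np.float64),
        time=clin["time"].to_numpy(dtype=np.float64),
        event=clin["event"].to_numpy(),
    )


def save_cohort(cohort: SurvivalCohort, expression_path: str | Path,
                clinical_path: str | Path, float_format: str = "%.10g") -> None:
    """Write the two TSVs `load_cohort` reads (lossless at the given precision)."""
    expr = pd.DataFrame(cohort.X, columns=cohort.genes)
    expr.insert(0, "sample_id", cohort.sample_ids)
    expr.to_csv(expression_path, sep="\t", index=False, float_format=float_format)
    clin = pd.DataFrame(
        {"sample_id": cohort.sample_ids, "time": cohort.time, "event": cohort.event}
    )
    clin.to_csv(clinical_path, sep="\t", index=False, float_format=float_format)


def align_to_signature(
    cohort: SurvivalCohort, sig: GeneSignature
) -> tuple[SurvivalCohort, AlignmentReport]:
    """Restrict a cohort to the signature genes it carries, in signature order."""
    index = {g: i for i, g in enumerate(cohort.genes)}
    present = [g for g in sig.genes if g in index]
    absent = [g for g in sig.genes if g not in index]
    if not present:
        raise CohortValidationError("no signature gene is present in the cohort")
    cols = [index[g] for g in present]
    aligned = SurvivalCohort(
        list(cohort.sample_ids), present, cohort.X[:, cols], cohort.time, cohort.event
    )
    return aligned, AlignmentReport(present=present, absent=absent)


def fit_standardizer(cohort: SurvivalCohort, train_rows) -> Standardizer:
    """Per-gene z-score statistics from the training rows only (no leakage)."""
    rows = np.asarray(train_rows)
    if rows.size == 0:
        raise CohortValidationError("cannot fit standardizer on an empty row set")
    Xtr = cohort.X[rows]
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return Standardizer(mean=mean, scale=sd)


def apply_standardizer(std: Standardizer, cohort: SurvivalCohort) -> SurvivalCohort:
    return SurvivalCohort(
        list(cohort.sample_ids),
        list(cohort.genes),
        std.transform(cohort.X),
        cohort.time,
        cohort.event,
    )
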