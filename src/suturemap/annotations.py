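"""Multi-rater subtype annotations: storage, agreement, ground truths.

Several physicians label the same cases independently and often disagree, so
the pipeline keeps one ground truth per rater rather than forcing a
consensus.  This module stores the case x rater label matrix, computes the
raters' overlap/disagreement rates, and derives per-rater or majority-vote
ground-truth maps.  ``unlabeled`` is a first-class value meaning the rater
declined to commit; such entries never count toward agreement and are
dropped from training label maps.

Percentages are computed in exact rational arithmetic and reported rounded
to two decimals, so ``overlap_rate + disagreement_rate == 100`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .errors import ValidationError
from .phantom import SUBTYPES

__all__ = ["LABELS", "UNLABELED", "AnnotationSet"]

UNLABELED = "unlabeled"
LABELS = SUBTYPES + (UNLABELED,)


@dataclass(frozen=True)
class AnnotationSet:
    """A complete case x rater label matrix.

    ``table`` is a DataFrame indexed by case id with one column per rater;
    every cell holds one of the four subtypes or ``"unlabeled"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.table.values.ravel()) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}; allowed: {LABELS}")
        if self.table.isna().any().any():
            raise ValidationError("every (case, rater) pair needs exactly one entry")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "AnnotationSet":
        """Build from long format with columns ``case_id, rater_id, label``."""
        required = {"case_id", "rater_id", "label"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"long format needs columns {sorted(required)}")
        if frame.duplicated(["case_id", "rater_id"]).any():
            raise ValidationError("duplicate (case, rater) entries")
        table = frame.pivot(index="case_id", columns="rater_id", values="label")
        if table.isna().any().any():
            raise ValidationError("every (case, rater) pair needs exactly one entry")
        return cls(table=table)

    @classmethod
    def from_csv(cls, path) -> "AnnotationSet":
        return cls.from_long(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        long = self.table.stack().rename("label").reset_index()
        long.columns = ["case_id", "rater_id", "label"]
        long.to_csv(path, index=False)

    # -- basic accessors ---------------------------------------------------

    @property
    def cases(self) -> list:
        return list(self.table.index)

    @property
    def raters(self) -> list:
        return list(self.table.columns)

    # -- agreement ---------------------------------------------------------

    def _concordant_cases(self) -> pd.Series:
        """Per case: do all raters give the same non-unlabeled label?"""
        same = self.table.nunique(axis=1) == 1
        labeled = (self.table != UNLABELED).all(axis=1)
        return same & labeled

    def overlap_fraction(self) -> Fraction:
        if len(self.raters) < 2:
            raise ValidationError("overlap rate needs at least two raters")
        if len(self.cases) == 0:
            raise ValidationError("overlap rate is undefined for zero cases")
        return Fraction(int(self._concordant_cases().sum()), len(self.cases))

    def overlap_rate(self) -> float:
        """Percent of cases on which *all* raters agree on a real subtype."""
        return round(float(100 * self.overlap_fraction()), 2)

    def disagreement_rate(self) -> float:
        """100 minus the overlap rate, computed on the same exact fraction."""
        return round(float(100 * (1 - self.overlap_fraction())), 2)

    # -- ground truths -----------------------------------------------------

    def per_rater_labels(self, rater) -> dict:
        """One rater's ground truth: case -> subtype, unlabeled cases dropped."""
        if rater not in self.table.columns:
            raise KeyError(f"unknown rater {rater!r}; raters: {self.raters}")
        col = self.table[rater]
        return {case: lab for case, lab in col.items() if lab != UNLABELED}

    def majority_vote(self) -> dict:
        """Consensus ground truth: cases where >= 2 raters agree on a subtype.

        Cases with no such majority (including all-unlabeled cases) are
        excluded; with >= 3 raters a tie between two subtypes at two votes
        each is ambiguous and also excluded.
        """
        if len(self.raters) < 3:
            raise ValidationError("majority vote needs at least three raters")
        out: dict = {}
        for case, row in self.table.iterrows():
            counts = row[row != UNLABELED].value_counts()
            top = counts[counts >= 2]
            if len(top) == 1:
                out[case] = top.index[0]
        return out
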