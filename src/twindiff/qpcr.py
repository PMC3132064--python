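"""ΔΔCt relative quantification and microarray/qPCR trend concordance.

Real-time PCR threshold cycles (Ct) for a target gene are normalized to a
reference gene (GAPDH) within each record, ``dCt = mean(Ct_target) -
mean(Ct_reference)``; the relative quantity of a case group against a
calibrator group is ``RQ = 2**-(dCt_case - dCt_calibrator)``.  A qPCR fold
and a microarray fold for the same gene are *trend concordant* when they
agree in sign and both magnitudes reach a minimum fold (default 1.1 — below
that, an assay is read as detecting no difference).

Signed-fold display convention throughout: a ratio r >= 1 is shown as r and
r < 1 as -1/r, so magnitudes are always >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ParameterError, ValidationError


@dataclass(frozen=True)
class CtRecord:
    """Replicate threshold cycles for one gene in one sample group."""

    gene: str
    group: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, cts in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not cts:
                raise ValidationError(f"{self.gene}/{self.group}: no {name} replicates")
            if any(not (0 < c <= 40) for c in cts):
                raise ValidationError(
                    f"{self.gene}/{self.group}: {name} Ct outside (0, 40]"
                )

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def rq(ct_case: CtRecord, ct_calibrator: CtRecord) -> float:
    """Relative quantity of case vs calibrator, ``2**-(ddCt)``."""
    if ct_case.gene != ct_calibrator.gene:
        raise ParameterError(
            f"gene mismatch: {ct_case.gene!r} vs {ct_calibrator.gene!r}"
        )
    ddct = ct_case.delta_ct - ct_calibrator.delta_ct
    return float(2.0 ** (-ddct))


def ratio_to_signed(ratio: float) -> float:
    """Fold ratio -> signed fold (r if r >= 1 else -1/r)."""
    if ratio <= 0:
        raise ParameterError("fold ratio must be positive")
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


def signed_to_ratio(fold: float) -> float:
    if -1 < fold < 1:
        raise ParameterError("signed folds never lie in (-1, 1)")
    return float(fold) if fold >= 1 else float(-1.0 / fold)


def trend_concordant(fold_a: float, fold_b: float, min_mag: float = 1.1) -> bool:
    """Same direction of regulation with both magnitudes >= ``min_mag``."""
    for f in (fold_a, fold_b):
        if -1 < f < 1:
            raise ParameterError(
                f"fold {f} violates the signed-fold convention (|fold| >= 1)"
            )
    return bool(
        np.sign(fold_a) == np.sign(fold_b)
        and abs(fold_a) >= min_mag
        and abs(fold_b) >= min_mag
    )


@dataclass(frozen=True)
class ConcordanceRow:
    gene: str
    rq_fold: float
    array_fold: float

    def concordant(self, min_mag: float = 1.1) -> bool:
        return trend_concordant(self.rq_fold, self.array_fold, min_mag)


def count_concordant(rows: Sequence[ConcordanceRow], min_mag: float = 1.1) -> int:
    """Number of genes whose qPCR and microarray folds share the trend."""
    if not rows:
        raise ParameterError("no concordance rows")
    return sum(r.concordant(min_mag) for r in rows)


def concordance_table(
    rows: Sequence[ConcordanceRow], min_mag: float = 1.1
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "rq_fold": [r.rq_fold for r in rows],
            "array_fold": [r.array_fold for r in rows],
            "concordant": [r.concordant(min_mag) for r in rows],
        }
    )


def read_ct_table(path) -> list[CtRecord]:
    """Read a Ct TSV: gene, group, ct_target, ct_reference (';'-separated reps)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"gene", "group", "ct_target", "ct_reference"}
    missing = needed - set(df.columns)
    if missing:
        raise ParameterError("Ct table missing column(s): " + ", ".join(sorted(missing)))
    out = []
    for r in df.itertuples(index=False):
        out.append(
            CtRecord(
                gene=r.gene,
                group=r.group,
                ct_target=tuple(float(x) for x in str(r.ct_target).split(";")),
                ct_reference=tuple(float(x) for x in str(r.ct_reference).split(";")),
            )
        )
    return out
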