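"""Two-mechanism decomposition of endo-lysosomal disruption.

For each compound, Gal8 foci per cell are regressed on DiD puncta per
cell across replicate-averaged wells, pooling ordinary wells with
endocytosis-blocker wells (which sit at zero uptake and anchor the
intercept).  The slope is the efficiency of colloid-mediated disruption
(foci per punctum of uptake); the intercept is the disruption that
occurs with no colloid uptake at all, attributed to free drug entering
by passive diffusion.  Per-compound estimates are then correlated across
the compound set with phospholipidosis (NBD-PE vesicles per cell) to ask
which mechanism tracks lysosomal phospholipid accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class MechanismFit:
    compound: str
    slope: float                 # foci per punctum
    slope_se: float
    intercept: float             # foci per cell at zero uptake
    intercept_se: float
    r_squared: float
    n_points: int


@dataclass
class CompoundSummary:
    compound: str
    pka: float
    slope: float
    intercept: float
    vesicles_per_cell: float


@dataclass
class CorrelationResult:
    pairing: str                 # which estimate was correlated
    r: float
    n: int


@dataclass
class SummaryJoin:
    """Join result: complete rows plus a report of ids missing from any
    input (never silently dropped)."""

    summaries: list[CompoundSummary]
    missing: dict[str, list[str]]


def fit_mechanism(wells: pd.DataFrame, compound: str | None = None
                  ) -> MechanismFit:
    """Ordinary least squares of foci_per_cell on puncta_per_cell.

    ``wells`` needs columns ``puncta_per_cell`` and ``foci_per_cell``
    (one row per replicate-averaged well, blocker wells included at
    x = 0) and, unless ``compound`` is given, a single-valued
    ``compound`` column.
    """
    if compound is None:
        ids = wells["compound"].unique() if "compound" in wells else [""]
        if len(ids) != 1:
            raise ValueError(
                f"wells table mixes compounds {sorted(ids)}; "
                "fit one compound at a time"
            )
        compound = str(ids[0])
    x = np.asarray(wells["puncta_per_cell"], dtype=float)
    y = np.asarray(wells["foci_per_cell"], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 wells to fit the regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: uptake has no variation")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return MechanismFit(
        compound=compound,
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        intercept=float(res.params[0]), intercept_se=float(res.bse[0]),
        r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
        n_points=int(x.size),
    )


def fit_mechanism_panel(panel: pd.DataFrame) -> list[MechanismFit]:
    """One regression per compound in a tidy multi-compound panel."""
    return [
        fit_mechanism(group, compound=str(cid))
        for cid, group in panel.groupby("compound", sort=True)
    ]


PAIRING_EFFICIENCY = "efficiency-vs-phospholipidosis"
PAIRING_INTERCEPT = "intercept-vs-phospholipidosis"


def correlate_mechanism(
    summaries: list[CompoundSummary], pairing: str
) -> CorrelationResult:
    """Pearson correlation of phospholipidosis with one mechanism
    estimate across compounds."""
    if pairing == PAIRING_EFFICIENCY:
        est = np.array([s.slope for s in summaries], dtype=float)
    elif pairing == PAIRING_INTERCEPT:
        est = np.array([s.intercept for s in summaries], dtype=float)
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    ves = np.array([s.vesicles_per_cell for s in summaries], dtype=float)
    if est.size < 3:
        raise ValueError("need at least 3 compounds to correlate")
    if not (np.isfinite(est).all() and np.isfinite(ves).all()):
        raise ValueError("non-finite estimates in correlation input")
    if np.ptp(est) == 0 or np.ptp(ves) == 0:
        raise ValueError("zero variance in correlation input")
    r = float(stats.pearsonr(ves, est).statistic)
    return CorrelationResult(pairing=pairing, r=r, n=int(est.size))


def build_compound_summary(
    mechanism_fits: list[MechanismFit],
    pka_by_compound: dict[str, float],
    vesicles_by_compound: dict[str, float],
) -> SummaryJoin:
    """Join mechanism fits, pKa fits, and phospholipidosis means into one
    row per compound.  Compounds absent from any input are listed in the
    report rather than silently dropped; duplicate ids are an error.
    """
    ids = [f.compound for f in mechanism_fits]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids in mechanism fits: {dupes}")
    all_ids = sorted(set(ids) | set(pka_by_compound) | set(vesicles_by_compound))
    missing = {
        "mechanism": [i for i in all_ids if i not in set(ids)],
        "pka": [i for i in all_ids if i not in pka_by_compound],
        "phospholipidosis": [i for i in all_ids if i not in vesicles_by_compound],
    }
    complete = [
        i for i in all_ids
        if i in set(ids) and i in pka_by_compound and i in vesicles_by_compound
    ]
    by_id = {f.compound: f for f in mechanism_fits}
    summaries = [
        CompoundSummary(
            compound=i,
            pka=float(pka_by_compound[i]),
            slope=by_id[i].slope,
            intercept=by_id[i].intercept,
            vesicles_per_cell=float(vesicles_by_compound[i]),
        )
        for i in complete
    ]
    return SummaryJoin(summaries=summaries, missing=missing)
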