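"""Parameter consistency across choice-set subsets.

Fits a model separately to each effect subset of a tailored dataset (delay
duration, common difference, magnitude) and interval-estimates, for every
parameter and pair of subsets, the across-participant correlation between
the per-subset individual estimates.  A correlation is flagged "credible"
when its 95% interval excludes zero.

Interval construction: with MCMC fits the correlation is computed draw-wise
(at each retained draw index, correlate participants' values between the
two subsets) and summarized by 2.5/97.5 percentiles, yielding a genuine
credible interval.  With MAP fits, the correlation of the point estimates
is reported with a seeded bootstrap percentile interval.  Correlations use
the unconstrained parameter scale, matching the recovery module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .estimation import Prior, SamplerConfig, default_prior, fit_individual
from .models import get_model
from .population import ChoiceDataset

__all__ = ["SubsetFits", "ConsistencyResult", "fit_by_subset",
           "cross_subset_correlations"]


@dataclass
class SubsetFits:
    """Per participant x subset individual fits for one model."""

    model_id: str
    subsets: tuple[str, ...]
    participants: tuple[str, ...]
    fits: Dict[tuple[str, str], object]  # (pid, subset) -> PosteriorFit
    mode: str


@dataclass
class ConsistencyResult:
    """Correlation intervals per parameter and subset pair.

    ``table`` columns: parameter, pair, r, r_lo, r_hi, credible, defined.
    Zero-variance (undefined) correlations are flagged via ``defined`` and
    carry NaN, never silently propagated.
    """

    model_id: str
    table: pd.DataFrame

    def lookup(self, parameter: str, pair: str) -> pd.Series:
        t = self.table
        return t[(t["parameter"] == parameter) & (t["pair"] == pair)].iloc[0]


def fit_by_subset(model_id: str, dataset: ChoiceDataset,
                  mode: str = "map",
                  prior: Optional[Prior] = None,
                  config: Optional[SamplerConfig] = None) -> SubsetFits:
    """Independent individual-level fits per participant and subset.

    Participants missing any labelled subset are excluded with a warning.
    """
    get_model(model_id)
    subsets = tuple(dataset.subsets)
    if not subsets:
        raise ValueError("dataset has no subset labels")
    config = config or SamplerConfig(n_chains=1, n_warmup=500, n_draws=1000)
    prior = prior or default_prior(model_id)
    kept, fits = [], {}
    df = dataset.df
    for pid in dataset.participants:
        have = set(df.loc[df["participant_id"] == pid, "subset"])
        if not set(subsets) <= have:
            warnings.warn(f"participant {pid} missing subset(s) "
                          f"{sorted(set(subsets) - have)}; excluded")
            continue
        kept.append(pid)
        for sub in subsets:
            items, choices = dataset.for_participant(pid, sub)
            fits[(pid, sub)] = fit_individual(model_id, items, choices,
                                              prior=prior, config=config,
                                              mode=mode)
    return SubsetFits(model_id, subsets, tuple(kept), fits, mode)


def _interval_flags(r_point, r_lo, r_hi):
    defined = np.isfinite(r_point)
    credible = bool(defined and np.isfinite(r_lo) and np.isfinite(r_hi)
                    and (r_lo > 0 or r_hi < 0))
    return defined, credible


def cross_subset_correlations(subset_fits: SubsetFits,
                              n_boot: int = 2000, seed: int = 0,
                              level: float = 0.95) -> ConsistencyResult:
    """Across-participant correlations of per-subset estimates, per parameter
    and subset pair, with 95% intervals (draw-wise for MCMC fits, bootstrap
    for MAP fits).  Requires >= 3 participants common to the subsets."""
    model = get_model(subset_fits.model_id)
    subsets = subset_fits.subsets
    if len(subsets) < 2:
        raise ValueError(">=2 subsets required for cross-subset correlations")
    pids = subset_fits.participants
    if len(pids) < 3:
        raise ValueError(">=3 participants required for correlations")
    lo_q, hi_q = 50 * (1 - level), 100 - 50 * (1 - level)
    P = model.n_params
    rng = np.random.default_rng(seed)
    rows = []
    for sub_a, sub_b in combinations(subsets, 2):
        # (J, P) point estimates and (J, S, P) draws per subset, u-scale
        u_a = np.stack([subset_fits.fits[(pid, sub_a)].median_u() for pid in pids])
        u_b = np.stack([subset_fits.fits[(pid, sub_b)].median_u() for pid in pids])
        if subset_fits.mode == "mcmc":
            da = np.stack([subset_fits.fits[(pid, sub_a)].draws_u.reshape(-1, P)
                           for pid in pids])  # (J, S, P)
            db = np.stack([subset_fits.fits[(pid, sub_b)].draws_u.reshape(-1, P)
                           for pid in pids])
            S = min(da.shape[1], db.shape[1])
        for j, name in enumerate(model.param_names):
            a, b = u_a[:, j], u_b[:, j]
            if np.std(a) == 0 or np.std(b) == 0:
                rows.append({"parameter": name, "pair": f"{sub_a}/{sub_b}",
                             "r": np.nan, "r_lo": np.nan, "r_hi": np.nan,
                             "credible": False, "defined": False})
                continue
            r_point = float(np.corrcoef(a, b)[0, 1])
            if subset_fits.mode == "mcmc":
                rs = np.empty(S)
                for s in range(S):
                    x, y = da[:, s, j], db[:, s, j]
                    rs[s] = (np.corrcoef(x, y)[0, 1]
                             if np.std(x) > 0 and np.std(y) > 0 else np.nan)
                rs = rs[np.isfinite(rs)]
            else:
                J = len(pids)
                rs = np.empty(n_boot)
                for s in range(n_boot):
                    idx = rng.integers(J, size=J)
                    x, y = a[idx], b[idx]
                    rs[s] = (np.corrcoef(x, y)[0, 1]
                             if np.std(x) > 0 and np.std(y) > 0 else np.nan)
                rs = rs[np.isfinite(rs)]
            r_lo = float(np.percentile(rs, lo_q)) if len(rs) else np.nan
            r_hi = float(np.percentile(rs, hi_q)) if len(rs) else np.nan
            defined, credible = _interval_flags(r_point, r_lo, r_hi)
            rows.append({"parameter": name, "pair": f"{sub_a}/{sub_b}",
                         "r": r_point, "r_lo": r_lo, "r_hi": r_hi,
                         "credible": credible, "defined": bool(defined)})
    return ConsistencyResult(subset_fits.model_id, pd.DataFrame(rows))
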