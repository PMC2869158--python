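"""Multiple imputation and bootstrap resampling (Step 2).

Missing covariate values are imputed m times (default 10) by chained
equations via statsmodels' ``MICEData``, using predictive mean matching
(donor pool 5) for every variable — PMM draws observed donor values, so
ordinal clinical covariates keep their support {1, 2, 3} without a
dedicated ordinal imputer.  The imputation models additionally condition
on the event indicator and the Nelson-Aalen cumulative-hazard estimate of
the outcome, the standard auxiliary pair for survival data.  The m
completed datasets are successive states of one chain separated by
``n_iterations`` full cycles.

Screened transformations are then applied (with scaling, cutpoints and
quartiles frozen from screening), and B bootstrap samples (default 100)
are drawn from each completed dataset, giving m x B sample datasets with
fully deterministic provenance from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .forms import Form, column_names, form_columns


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 10
    n_iterations: int = 20
    seed: int = 0
    k_pmm: int = 5

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_iterations < 5:
            raise ValueError("chained-equation chains need >= 5 iterations")


def nelson_aalen(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's own time."""
    from lifelines import NelsonAalenFitter

    naf = NelsonAalenFitter().fit(time, event)
    return naf.cumulative_hazard_at_times(time).to_numpy(dtype=float)


def mice_impute(cohort: pd.DataFrame, variables: list[str],
                config: ImputationConfig = ImputationConfig(),
                time_col: str = "time_rfs", event_col: str = "event_rfs",
                ) -> list[pd.DataFrame]:
    """Return m completed copies of *cohort* (observed entries untouched)."""
    from statsmodels.imputation.mice import MICEData

    missing = cohort[variables].isna()
    frac = missing.mean()
    if (frac >= 1.0).any():
        bad = frac.index[frac >= 1.0].tolist()
        raise ValueError(f"variables fully missing: {bad}")
    if (frac >= 0.5).any():
        bad = frac.index[frac >= 0.5].tolist()
        raise ValueError(f"variables with >=50% missingness: {bad}")
    if cohort[[time_col, event_col]].isna().any().any():
        raise ValueError("outcome columns must be complete")
    if not missing.to_numpy().any():
        return [cohort.copy() for _ in range(config.m)]

    work = cohort[variables].copy()
    work["_event"] = cohort[event_col].to_numpy(dtype=float)
    work["_cumhaz"] = nelson_aalen(
        cohort[time_col].to_numpy(dtype=float), cohort[event_col].to_numpy(dtype=int)
    )
    # MICEData uses the global numpy RNG; seed it for determinism
    np.random.seed(int(config.seed) % (2**31))
    md = MICEData(work.reset_index(drop=True), k_pmm=config.k_pmm)
    completed = []
    for _ in range(config.m):
        md.update_all(config.n_iterations)
        out = cohort.copy()
        out[variables] = md.data[variables].to_numpy(dtype=float)
        completed.append(out)
    return completed


def apply_forms(completed: pd.DataFrame, forms: dict[str, Form]) -> pd.DataFrame:
    """Design matrix from screened forms, parameters frozen from screening."""
    cols, names = [], []
    for var, form in forms.items():
        x = completed[var].to_numpy(dtype=float)
        cols.append(form_columns(x, form))
        names.extend(column_names(var, form))
    if not cols:
        return pd.DataFrame(index=completed.index)
    return pd.DataFrame(np.column_stack(cols), columns=names, index=completed.index)


def bootstrap_indices(n: int, B: int, seed: int, imp_index: int = 0) -> np.ndarray:
    """(B, n) resampling indices; rows derive from (seed, imp_index, b)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    out = np.empty((B, n), dtype=np.int64)
    for b in range(B):
        rng = np.random.default_rng([int(seed) % (2**31), imp_index, b])
        out[b] = rng.integers(0, n, size=n)
    return out


def draw_bootstrap(completed: pd.DataFrame, B: int, seed: int,
                   imp_index: int = 0) -> list[pd.DataFrame]:
    """B case-resampled copies of a completed dataset."""
    idx = bootstrap_indices(len(completed), B, seed, imp_index)
    return [completed.iloc[row].reset_index(drop=True) for row in idx]


@dataclass
class SampleSet:
    """m completed cohorts and their m x B bootstrap samples with provenance."""

    imputed: list[pd.DataFrame]
    indices: np.ndarray  # (m, B, n)
    seed: int

    @property
    def m(self) -> int:
        return len(self.imputed)

    @property
    def B(self) -> int:
        return self.indices.shape[1]

    @property
    def n_samples(self) -> int:
        return self.m * self.B

    def sample(self, imp: int, boot: int) -> pd.DataFrame:
        return self.imputed[imp].iloc[self.indices[imp, boot]].reset_index(drop=True)

    def __iter__(self) -> Iterator[tuple[int, int, pd.DataFrame]]:
        for i in range(self.m):
            for b in range(self.B):
                yield i, b, self.sample(i, b)


def build_sample_set(imputed: list[pd.DataFrame], B: int, seed: int) -> SampleSet:
    n = len(imputed[0])
    idx = np.stack([bootstrap_indices(n, B, seed, i) for i in range(len(imputed))])
    return SampleSet(imputed=imputed, indices=idx, seed=seed)
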