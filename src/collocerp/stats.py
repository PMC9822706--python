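"""Two-sample permutation independence test with a standardized linear statistic.

The test conditions on the observed amplitudes and asks whether their
assignment to the two conditions is exchangeable.  The linear statistic is
the sum of group-1 values, ``T = sum_{i in group 1} y_i``; under random
relabeling its conditional moments are

    E(T)   = n1 * mean(y)
    Var(T) = n1 * n2 / (n * (n - 1)) * sum((y - mean(y))^2)

and the standardized statistic is ``z = (T - E(T)) / sqrt(Var(T))``.  The
two-sided p-value is obtained from the asymptotic normal reference
(``2 * (1 - Phi(|z|))``), from Monte-Carlo resampling of label assignments
(add-one rule), or from exact enumeration of all label assignments for
small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

#: |z| comparisons in resampling use this relative guard so that exact ties
#: arising from permuted duplicates are counted as at-least-as-extreme.
_TIE_EPS = 1e-12

EXACT_N_MAX = 20


@dataclass
class PermutationResult:
    statistic_z: float
    p_asymptotic: float
    p_montecarlo: float | None
    p_exact: float | None
    n_permutations: int | None
    n1: int
    n2: int
    mode: str
    roi: str | None = None
    label: str | None = None
    seed: int | None = None

    @property
    def p_value(self) -> float:
        """The p-value of the requested mode."""
        if self.mode == "exact":
            return self.p_exact
        if self.mode == "montecarlo":
            return self.p_montecarlo
        return self.p_asymptotic


def _standardize(values: np.ndarray, mask1: np.ndarray) -> tuple[float, float, float]:
    """Return (T, E(T), sd(T)) for the group-1 sum under permutation."""
    n = len(values)
    n1 = int(mask1.sum())
    n2 = n - n1
    ybar = values.mean()
    t = float(values[mask1].sum())
    ss = float(((values - ybar) ** 2).sum())
    var = n1 * n2 / (n * (n - 1)) * ss
    return t, n1 * ybar, np.sqrt(var)


def independence_test(
    values,
    labels,
    mode: str = "asymptotic",
    B: int = 9999,
    seed: int | None = None,
    roi: str | None = None,
) -> PermutationResult:
    """Two-sample permutation test of condition independence.

    ``labels`` must take exactly two distinct values; group 1 is the first
    label in sorted order.  ``mode`` selects which p-value drives
    :attr:`PermutationResult.p_value`; the asymptotic one is always
    reported.  Exact enumeration is limited to ``n <= 20``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D")
    uniq = sorted(pd.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    mask1 = labels == uniq[0]
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("one group is empty")
    if mode not in ("asymptotic", "montecarlo", "exact"):
        raise ValueError(f"unknown mode {mode!r}")

    t, e_t, sd_t = _standardize(values, mask1)
    if sd_t == 0:
        warnings.warn("zero variance: statistic undefined, z set to 0", stacklevel=2)
        return PermutationResult(
            statistic_z=0.0, p_asymptotic=1.0,
            p_montecarlo=1.0 if mode == "montecarlo" else None,
            p_exact=1.0 if mode == "exact" else None,
            n_permutations=None, n1=n1, n2=n2, mode=mode, roi=roi,
            label=str(uniq[0]), seed=seed,
        )
    z = (t - e_t) / sd_t
    p_asym = float(2.0 * norm.sf(abs(z)))
    abs_dev = abs(t - e_t)
    guard = _TIE_EPS * max(1.0, abs_dev)

    p_mc = None
    p_exact = None
    n_perm = None
    if mode == "montecarlo":
        if seed is None:
            raise ValueError("montecarlo mode requires a seed")
        rng = np.random.default_rng(seed)
        # permute by drawing random group-1 index sets
        count = 0
        chunk = 10000
        done = 0
        while done < B:
            m = min(chunk, B - done)
            keys = rng.random((m, len(values)))
            idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
            t_perm = values[idx].sum(axis=1)
            count += int((np.abs(t_perm - e_t) >= abs_dev - guard).sum())
            done += m
        p_mc = (count + 1) / (B + 1)
        n_perm = B
    elif mode == "exact":
        n = len(values)
        if n > EXACT_N_MAX:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_N_MAX}")
        t_all = np.array(
            [values[list(c)].sum() for c in combinations(range(n), n1)]
        )
        p_exact = float(
            (np.abs(t_all - e_t) >= abs_dev - guard).mean()
        )
        n_perm = len(t_all)

    return PermutationResult(
        statistic_z=float(z), p_asymptotic=p_asym, p_montecarlo=p_mc,
        p_exact=p_exact, n_permutations=n_perm, n1=n1, n2=n2, mode=mode,
        roi=roi, label=str(uniq[0]), seed=seed,
    )


def condition_tests(
    table: pd.DataFrame,
    mode: str = "asymptotic",
    B: int = 9999,
    seed: int | None = None,
    bonferroni: bool = False,
) -> list[PermutationResult]:
    """One condition comparison per ROI on an amplitude table.

    The table needs columns ``roi``, ``condition``, ``amplitude_uv`` with
    both conditions present in every ROI.  No multiplicity correction is
    applied by default; ``bonferroni=True`` multiplies the driving p-value
    by the number of ROIs (capped at 1) in a ``p_corrected`` attribute.
    """
    results = []
    rois = list(pd.unique(table["roi"]))
    for k, roi_name in enumerate(rois):
        sub = table[table["roi"] == roi_name]
        conds = pd.unique(sub["condition"])
        if len(conds) != 2:
            raise ValueError(
                f"ROI {roi_name}: expected both conditions, got {list(conds)}"
            )
        res = independence_test(
            sub["amplitude_uv"].to_numpy(),
            sub["condition"].to_numpy(),
            mode=mode,
            B=B,
            seed=None if seed is None else seed + k,
            roi=roi_name,
        )
        if bonferroni:
            res.p_corrected = min(1.0, res.p_value * len(rois))
        results.append(res)
    return results


def site_comparison(
    table: pd.DataFrame,
    condition: str = "collocation",
    mode: str = "asymptotic",
    B: int = 9999,
    seed: int | None = None,
) -> tuple[list[PermutationResult], float]:
    """Pairwise ROI comparisons within one condition.

    Tests whether processing of ``condition`` items differs between
    recording sites: a two-sample permutation test for every ROI pair,
    plus the maximum |z| across pairs as a lateralization summary.
    """
    sub = table[table["condition"] == condition]
    rois = list(pd.unique(sub["roi"]))
    if len(rois) < 2:
        raise ValueError(f"need >= 2 sites with data for {condition!r}")
    results = []
    for k, (a, b) in enumerate(combinations(rois, 2)):
        va = sub.loc[sub["roi"] == a, "amplitude_uv"].to_numpy()
        vb = sub.loc[sub["roi"] == b, "amplitude_uv"].to_numpy()
        res = independence_test(
            np.concatenate([va, vb]),
            np.array([a] * len(va) + [b] * len(vb)),
            mode=mode,
            B=B,
            seed=None if seed is None else seed + k,
            roi=f"{a}-{b}",
        )
        results.append(res)
    max_abs_z = max(abs(r.statistic_z) for r in results)
    return results, float(max_abs_z)


def results_table(results: list[PermutationResult]) -> pd.DataFrame:
    rows = [
        {
            "roi": r.roi,
            "n1": r.n1,
            "n2": r.n2,
            "z": r.statistic_z,
            "p_asymptotic": r.p_asymptotic,
            "p_montecarlo": r.p_montecarlo,
            "p_exact": r.p_exact,
            "mode": r.mode,
            "B": r.n_permutations,
            "seed": r.seed,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
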