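"""Train/test evaluation protocol: replicated 90/10 splits and accuracy.

The protocol: fit each method to 90% of the lines, predict the held-out 10%,
score with the Pearson correlation r between observed and predicted
phenotypes, and repeat over 25 random splits; the per-method summary is the
mean r with its standard error over the replicates that produced a defined
correlation. A replicate fails when the model is intercept-only (constant
predictions have no correlation), fails to converge, or errors; a method
whose failure rate exceeds 40% in at least one analyzed stratum (e.g. sex)
is flagged ``excluded`` from comparison.

Every method in a comparison consumes the identical split plan, so
differences in r are attributable to the methods rather than the splits.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitPlan",
    "make_splits",
    "accuracy",
    "aggregate",
    "run_benchmark",
    "method_seed",
    "EXCLUSION_THRESHOLD",
]

EXCLUSION_THRESHOLD = 0.4


@dataclass
class SplitPlan:
    replicates: list[tuple[np.ndarray, np.ndarray]]
    n_reps: int
    test_fraction: float
    base_seed: int

    @property
    def plan_hash(self) -> str:
        h = hashlib.sha256()
        for tr, te in self.replicates:
            h.update(tr.tobytes())
            h.update(te.tobytes())
        return h.hexdigest()[:16]


def make_splits(
    n: int, n_reps: int = 25, test_fraction: float = 0.1, base_seed: int = 0
) -> SplitPlan:
    """Uniform random train/test partitions; replicate k is seeded base_seed+k.

    Test size is round(test_fraction * n) (nearest integer), e.g. 20 of 198
    lines at the default 10%.
    """
    if n < 20:
        raise ValueError("need at least 20 lines for a meaningful split plan")
    n_test = int(round(test_fraction * n))
    if n_test == 0:
        raise ValueError("test fraction rounds to an empty test set")
    reps = []
    for k in range(n_reps):
        rng = np.random.default_rng(base_seed + k)
        perm = rng.permutation(n)
        reps.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
    return SplitPlan(reps, n_reps, test_fraction, base_seed)


def accuracy(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[float, str | None]:
    """Pearson r between observed and predicted, or (nan, cause) when undefined.

    Constant predictions (intercept-only models) have zero variance and no
    correlation; this is a recorded failure, not an exception.
    """
    y_obs = np.asarray(y_obs, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_obs.shape != y_pred.shape:
        raise ValueError("length mismatch between observed and predicted")
    if len(y_obs) < 3:
        raise ValueError("need at least 3 test lines for a correlation")
    if not np.all(np.isfinite(y_pred)):
        return float("nan"), "non-finite prediction"
    if np.std(y_pred) == 0:
        return float("nan"), "zero-variance prediction"
    if np.std(y_obs) == 0:
        return float("nan"), "zero-variance observation"
    return float(np.corrcoef(y_obs, y_pred)[0, 1]), None


def aggregate(results: pd.DataFrame, n_reps: int | None = None) -> pd.DataFrame:
    """Per-method mean r, standard error, failure accounting and exclusion.

    ``results`` has columns ``method``, ``replicate``, ``r`` (NaN = failed)
    and optionally ``stratum`` (e.g. sex). Mean and SE (sample SD of r over
    successful replicates divided by sqrt(#successes)) ignore failures; the
    exclusion flag fires when failures exceed 40% of replicates in at least
    one stratum.
    """
    if results.empty:
        raise ValueError("no replicates supplied")
    df = results.copy()
    if "stratum" not in df.columns:
        df["stratum"] = "all"
    rows = []
    for method, grp in df.groupby("method", sort=False):
        excluded = False
        for _, sub in grp.groupby("stratum"):
            n_tot = n_reps if n_reps is not None else len(sub)
            frac_failed = sub["r"].isna().sum() / n_tot
            if frac_failed > EXCLUSION_THRESHOLD:
                excluded = True
        ok = grp["r"].dropna()
        n_tot = n_reps if n_reps is not None else len(grp)
        n_failed = int(grp["r"].isna().sum())
        rows.append({
            "method": method,
            "mean_r": float(ok.mean()) if len(ok) else float("nan"),
            "se_r": float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else
                    (0.0 if len(ok) == 1 else float("nan")),
            "n_success": int(len(ok)),
            "n_failed": n_failed,
            "failure_pct": 100.0 * n_failed / n_tot,
            "excluded": excluded or len(ok) == 0,
        })
    return pd.DataFrame(rows)


def method_seed(base_seed: int, replicate: int, name: str) -> int:
    """Deterministic per-(method, replicate) seed below 2^31.

    Methods share the split plan (same base seed) but never a sampler stream.
    """
    ss = np.random.SeedSequence([base_seed, replicate, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(
    X: np.ndarray,
    y: np.ndarray,
    methods: dict,
    plan: SplitPlan,
    configs: dict | None = None,
) -> pd.DataFrame:
    """Fit every method on every replicate of the shared plan.

    ``methods`` maps a name to an adapter
    ``fn(X_train, y_train, X_test, seed, **cfg) -> FitOutcome``; see
    :mod:`txpred.methods`. Returns the per-replicate table consumed by
    :func:`aggregate`, with the plan hash attached in ``attrs`` so shared
    splits are assertable downstream.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    configs = configs or {}
    rows = []
    for k, (tr, te) in enumerate(plan.replicates):
        for name, fn in methods.items():
            seed = method_seed(plan.base_seed, k, name)
            cfg = configs.get(name, {})
            try:
                outcome = fn(X[tr], y[tr], X[te], seed, **cfg)
            except Exception as exc:  # runtime errors are recorded failures
                rows.append({"method": name, "replicate": k, "r": float("nan"),
                             "failure_cause": f"runtime error: {exc}"})
                continue
            if outcome.failed:
                rows.append({"method": name, "replicate": k, "r": float("nan"),
                             "failure_cause": outcome.failure_cause})
                continue
            r, cause = accuracy(y[te], outcome.predictions)
            rows.append({"method": name, "replicate": k, "r": r,
                         "failure_cause": cause})
    out = pd.DataFrame(rows)
    out.attrs["plan_hash"] = plan.plan_hash
    return out
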