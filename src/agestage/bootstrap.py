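"""Bootstrap standard errors and the paired bootstrap comparison.

The resampling unit is the individual (the egg), preserving each individual's
entire recorded life history — the standard two-sex life-table bootstrap: every
replicate redraws N individuals with replacement and recomputes R0, r, lambda,
T and pre-adult survival with the life-table engine.  Replicate b of any run
draws its resampling indices from the sub-seeded stream ``(seed, b)``, so two
cohorts of equal size bootstrapped with the same seed share index streams and
their replicates are aligned — that alignment is what makes the paired test
paired (and makes a cohort compared against itself give exactly zero
differences).

Replicates in which no resampled female reproduces have R0 = 0 and an
undefined r/lambda/T; they are recorded as missing, counted, and excluded from
the summary statistics of the affected parameters.  Reported SEs are the
standard deviations of the replicate distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, cohort_arrays
from .lifetable import compute_demography, demography_from_phi

__all__ = [
    "PARAMETERS",
    "BootstrapResult",
    "PairedTestResult",
    "bootstrap_parameters",
    "paired_bootstrap_test",
    "compare_many",
    "compact_letter_display",
]

PARAMETERS = ("R0", "r", "lambda", "T", "preadult_survival")


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimates plus B aligned bootstrap replicates per parameter."""

    B: int
    seed: int
    label: str
    estimates: dict[str, float | None]
    samples: dict[str, np.ndarray]  # length B; NaN where undefined
    n_undefined: dict[str, int]
    se: dict[str, float]
    percentiles: dict[str, tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        """Replicates as a B-row DataFrame (for CSV round-tripping)."""
        return pd.DataFrame({p: self.samples[p] for p in PARAMETERS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, B: int | None = None, seed: int = -1,
                   label: str = "", estimates: dict | None = None) -> "BootstrapResult":
        samples = {p: df[p].to_numpy(dtype=float) for p in PARAMETERS}
        B = len(df) if B is None else B
        est = estimates or {p: float(np.nanmean(samples[p])) for p in PARAMETERS}
        return cls(B, seed, label, est, samples,
                   {p: int(np.isnan(samples[p]).sum()) for p in PARAMETERS},
                   _se(samples), _pct(samples))


def _se(samples: dict[str, np.ndarray]) -> dict[str, float]:
    out = {}
    for p, v in samples.items():
        d = v[~np.isnan(v)]
        out[p] = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return out


def _pct(samples: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    out = {}
    for p, v in samples.items():
        d = v[~np.isnan(v)]
        if d.size:
            lo, hi = np.percentile(d, [2.5, 97.5])
            out[p] = (float(lo), float(hi))
        else:
            out[p] = (np.nan, np.nan)
    return out


def bootstrap_parameters(cohort: Cohort, B: int = 100_000, seed: int = 0) -> BootstrapResult:
    """Bootstrap all demographic parameters of a cohort.

    The default B follows the convention of large life-table studies (1e5);
    a few thousand replicates give stable SEs for testing purposes.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arrs = cohort_arrays(cohort)
    N = arrs.N
    eggs = arrs.eggs  # (N, n_ages); l_x m_x of a resample is its column mean
    reached = arrs.reached_adult.astype(float)

    point = compute_demography(cohort)
    samples = {p: np.full(B, np.nan) for p in PARAMETERS}
    for b in range(B):
        idx = np.random.default_rng([seed, b]).integers(0, N, N)
        phi = eggs[idx].sum(axis=0) / N
        R0, r, lam, T = demography_from_phi(phi)
        samples["R0"][b] = R0
        samples["r"][b] = r
        samples["lambda"][b] = lam
        samples["T"][b] = T
        samples["preadult_survival"][b] = reached[idx].mean()

    return BootstrapResult(
        B=B,
        seed=seed,
        label=cohort.label,
        estimates=point.as_dict(),
        samples=samples,
        n_undefined={p: int(np.isnan(samples[p]).sum()) for p in PARAMETERS},
        se=_se(samples),
        percentiles=_pct(samples),
    )


@dataclass(frozen=True)
class PairedTestResult:
    """Per-parameter paired bootstrap comparison of two cohorts."""

    labels: tuple[str, str]
    difference: dict[str, float]  # point-estimate difference a - b
    se: dict[str, float]  # SD of the replicate differences
    p_value: dict[str, float]
    n_defined: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(PARAMETERS),
                "difference": [self.difference[p] for p in PARAMETERS],
                "se": [self.se[p] for p in PARAMETERS],
                "p_value": [self.p_value[p] for p in PARAMETERS],
                "n_defined": [self.n_defined[p] for p in PARAMETERS],
            }
        )


def paired_bootstrap_test(a: BootstrapResult, b: BootstrapResult) -> PairedTestResult:
    """Percentile-based two-sided paired test on aligned replicate differences.

    ``p = 2 * min(P(d <= 0), P(d >= 0))`` with add-one smoothing
    ``(k + 1) / (n + 1)``, capped at 1.  Replicates where either side is
    undefined are dropped (their count is reported via ``n_defined``).
    """
    if a.B != b.B:
        raise ValueError(f"mismatched replicate counts: {a.B} != {b.B}")
    diff, se, pval, ndef = {}, {}, {}, {}
    for p in PARAMETERS:
        d = a.samples[p] - b.samples[p]
        d = d[~np.isnan(d)]
        n = d.size
        ndef[p] = n
        ea, eb = a.estimates[p], b.estimates[p]
        diff[p] = (ea - eb) if (ea is not None and eb is not None) else np.nan
        se[p] = float(np.std(d, ddof=1)) if n > 1 else 0.0
        if n == 0:
            pval[p] = np.nan
            continue
        k_le = int(np.sum(d <= 0))
        k_ge = int(np.sum(d >= 0))
        pval[p] = min(1.0, 2.0 * min(k_le + 1, k_ge + 1) / (n + 1))
    return PairedTestResult((a.label, b.label), diff, se, pval, ndef)


def compact_letter_display(
    names: list[str], means: dict[str, float], sig: dict[tuple[str, str], bool]
) -> dict[str, str]:
    """Assign letters so groups sharing a letter are not significantly different.

    Letters label the maximal cliques of the non-significance graph, ordered by
    descending group mean (the convention of agricultural statistics software).
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    for (x, y), s in sig.items():
        if not s:
            g.add_edge(x, y)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[n] for n in c))
    letters = {n: "" for n in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for n in sorted(clique, key=lambda n: -means[n]):
            letters[n] += alphabet[i % len(alphabet)]
    return {n: "".join(sorted(letters[n])) for n in names}


def compare_many(
    results: dict[str, BootstrapResult], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs paired bootstrap tests with Holm-adjusted letters per parameter.

    Returns a tidy table (parameter, group, estimate, se, ci_low, ci_high,
    letter) of the style used for published demographic-parameter tables.
    """
    names = list(results)
    rows = []
    for p in PARAMETERS:
        pairs = [(x, y) for i, x in enumerate(names) for y in names[i + 1 :]]
        raw = []
        for x, y in pairs:
            raw.append(paired_bootstrap_test(results[x], results[y]).p_value[p])
        if pairs:
            raw_arr = np.asarray(raw, dtype=float)
            ok = ~np.isnan(raw_arr)
            rej = np.zeros(len(pairs), dtype=bool)
            if ok.any():
                rej[ok] = multipletests(raw_arr[ok], alpha=alpha, method="holm")[0]
            sig = {pair: bool(r) for pair, r in zip(pairs, rej)}
        else:
            sig = {}
        means = {
            n: (results[n].estimates[p] if results[n].estimates[p] is not None else -np.inf)
            for n in names
        }
        letters = compact_letter_display(names, means, sig) if len(names) > 1 else {
            n: "a" for n in names
        }
        for n in names:
            est = results[n].estimates[p]
            lo, hi = results[n].percentiles[p]
            rows.append(
                {
                    "parameter": p,
                    "group": n,
                    "estimate": est,
                    "se": results[n].se[p],
                    "ci_low": lo,
                    "ci_high": hi,
                    "letter": letters[n],
                }
            )
    return pd.DataFrame(rows)
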