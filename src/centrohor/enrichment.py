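"""Positional enrichment of HOR pattern classes along an array.

The array is split into equal-width bins (default 25); every annotated HOR
instance is assigned to the bin containing its midpoint.  For each pattern
class, the same number of instances is re-placed uniformly at random
``n_random`` times (default 100) to form a background; per (bin, class)
the z score ``(N_obv - mu) / sigma`` and a one-sided upper-tail normal
p-value flag bins where the class is enriched.  Bins whose background has
zero variance are reported untestable (NA) rather than as infinite z.
No multiple-testing correction is applied; p-values are per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["bin_instances", "enrichment_test", "EnrichmentResult"]


def bin_instances(
    instances: list[tuple[int, int, str]],
    region: tuple[int, int],
    n_bins: int = 25,
) -> pd.DataFrame:
    """Per-(bin, class) observed counts; an instance lives in its midpoint's bin.

    ``instances`` are (start, end, class_label) with half-open coordinates
    inside ``region``.
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError("empty region")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    width = (hi - lo) / n_bins
    classes = sorted({c for _, _, c in instances})
    counts = {c: np.zeros(n_bins, dtype=int) for c in classes}
    for start, end, cls in instances:
        if start < lo or end > hi:
            raise ValueError(f"instance [{start}, {end}) outside region {region}")
        mid = (start + end) / 2
        b = min(int((mid - lo) / width), n_bins - 1)
        counts[cls][b] += 1
    rows = [
        {"bin": b, "class": c, "n_obv": int(counts[c][b])}
        for c in classes
        for b in range(n_bins)
    ]
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Per-(bin, class) observed counts, background moments, z and p."""

    n_bins: int
    n_random: int
    table: pd.DataFrame  # bin, class, n_obv, mu, sigma, z, p, enriched


def enrichment_test(
    counts: pd.DataFrame,
    n_bins: int = 25,
    n_random: int = 100,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Uniform-placement background and one-sided z test per (bin, class)."""
    rng = rng or np.random.default_rng()
    out_rows = []
    for cls, sub in counts.groupby("class", sort=True):
        obs = np.zeros(n_bins, dtype=int)
        obs[sub["bin"].to_numpy()] = sub["n_obv"].to_numpy()
        total = int(obs.sum())
        if total < 1:
            raise ValueError(f"class {cls!r} has no instances")
        bg = np.empty((n_random, n_bins), dtype=int)
        for r in range(n_random):
            placed = rng.integers(0, n_bins, size=total)
            bg[r] = np.bincount(placed, minlength=n_bins)
        mu = bg.mean(axis=0)
        sigma = bg.std(axis=0, ddof=0)
        for b in range(n_bins):
            if sigma[b] == 0:
                z = p = float("nan")
                enriched = False
            else:
                z = (obs[b] - mu[b]) / sigma[b]
                p = float(norm.sf(z))
                enriched = p < alpha
            out_rows.append(
                {
                    "bin": b,
                    "class": cls,
                    "n_obv": int(obs[b]),
                    "mu": float(mu[b]),
                    "sigma": float(sigma[b]),
                    "z": float(z) if not np.isnan(z) else np.nan,
                    "p": p,
                    "enriched": enriched,
                }
            )
    return EnrichmentResult(
        n_bins=n_bins, n_random=n_random, table=pd.DataFrame(out_rows)
    )
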