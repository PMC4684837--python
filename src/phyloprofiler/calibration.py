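"""Calibration of the profile-similarity threshold on random profiles.

The p0 cutoff is meant to make chance profile similarity vanishingly rare:
at the published operating point (panel of ~1200 genomes, p0 = 1e-7), no
more than about one in 1e7 comparisons of two independent random profiles
should fall below the cutoff. Because the hypergeometric test is exact,
this holds for any profile densities; the calibration here measures it
empirically by streaming random profile pairs through the same comparison
code the annotator uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import compare_profiles
from .config import as_rng
from .profiles import PhylogeneticProfile
from .simulate import generate_random_profiles

__all__ = ["CalibrationResult", "calibrate_p0"]


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a p0 calibration run on random profile pairs."""

    n_comparisons: int
    N: int
    p0: float
    count_below: int

    @property
    def rate(self) -> float:
        return self.count_below / self.n_comparisons


def calibrate_p0(
    n_comparisons: int,
    N: int = 1204,
    density_range: tuple[float, float] = (0.05, 0.5),
    p0: float = 1e-7,
    rng: int | np.random.Generator | None = None,
    batch_size: int = 20_000,
) -> CalibrationResult:
    """Count random profile pairs whose similarity P falls below ``p0``.

    Pairs are generated in batches (each vector with its own density drawn
    from ``density_range``) and compared with :func:`compare_profiles`.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    gen = as_rng(rng)
    count = 0
    done = 0
    while done < n_comparisons:
        n = min(batch_size, n_comparisons - done)
        a, b = generate_random_profiles(n, N, density_range, gen)
        for i in range(n):
            cmp_ = compare_profiles(
                PhylogeneticProfile("a", a[i]), PhylogeneticProfile("b", b[i])
            )
            if cmp_.P < p0:
                count += 1
        done += n
    return CalibrationResult(
        n_comparisons=n_comparisons, N=N, p0=p0, count_below=count
    )
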