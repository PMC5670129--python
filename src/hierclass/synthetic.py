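"""Synthetic fixtures with known ground truth.

Two generators stand in for real profiling data so that every stage of the
package is testable without downloads:

* :func:`gen_hierarchical_gaussians` emulates a class taxonomy over a feature
  matrix — class means branch recursively, children scattering around their
  parent's mean at a controlled separation (in units of the within-class
  standard deviation), samples drawn isotropically around the leaf means.
  Separation 6 sigma makes the Bayes error effectively zero; separation 0
  collapses all classes onto one distribution (a permutation null).

* :func:`gen_synthetic_spectra` emulates profile mass spectra: planted Gaussian
  peaks per class with per-spectrum m/z jitter, multiplicative scale factors
  (ion-yield variation between acquisitions) and an additive noise floor.

Both are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hierarchy as hi
from .hierarchy import HierarchyTree
from .ms_preprocess import Spectrum


def _unit(rng: np.random.Generator, d: int) -> np.ndarray:
    u = rng.standard_normal(d)
    return u / np.linalg.norm(u)


@dataclass
class TreeSpec:
    """Shape and signal strength of a synthetic hierarchy."""

    branching: list[int] = field(default_factory=lambda: [2, 3, 2])
    samples_per_leaf: int = 30
    n_features: int = 50
    separation: "list[float] | float" = 6.0  # per level, units of sigma
    sigma: float = 1.0
    seed: int = 0
    heteroscedastic: bool = False  # noise sd grows with |mean| (MS-like)
    orthogonal_means: bool = True  # offsets mutually orthogonal (guaranteed
    # separation); False scatters along random directions instead

    def __post_init__(self):
        if any(b < 1 for b in self.branching):
            raise ValueError("branching factors must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.isscalar(self.separation):
            self.separation = [float(self.separation)] * len(self.branching)
        if len(self.separation) != len(self.branching):
            raise ValueError("one separation per level required")
        if any(s < 0 for s in self.separation):
            raise ValueError("separations must be >= 0")

    @property
    def n_offsets(self) -> int:
        """Total non-root nodes = offset directions the mean layout needs."""
        total, width = 0, 1
        for b in self.branching:
            width *= b
            total += width
        return total


def gen_hierarchical_gaussians(
    spec: TreeSpec,
) -> tuple[np.ndarray, list[tuple], HierarchyTree]:
    """Generate ``(X, lineages, tree)`` with recursively branching class means.

    Child means sit at distance ``separation[level] * sigma`` from the parent
    mean.  By default every node's offset direction is drawn from one random
    orthonormal frame, so "separation 6 sigma" is a guaranteed minimum distance
    between any two class means at that level (siblings end up sqrt(2) x apart)
    and the Bayes error at large separations is genuinely near zero.  With
    ``orthogonal_means=False`` directions are independent random unit vectors,
    which in low dimension can place unrelated branches arbitrarily close.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_features
    if spec.orthogonal_means:
        if d < spec.n_offsets:
            raise ValueError(
                f"orthogonal mean layout needs n_features >= {spec.n_offsets} "
                f"(one direction per class node); got {d}"
            )
        Q, _ = np.linalg.qr(rng.standard_normal((d, spec.n_offsets)))
        directions = iter(Q.T)
    else:

        def _random_directions():
            while True:
                yield _unit(rng, d)

        directions = _random_directions()

    def offspring(mean: np.ndarray, level: int, path: tuple):
        if level == len(spec.branching):
            return [(path, mean)]
        leaves = []
        for i in range(spec.branching[level]):
            u = next(directions)
            child_mean = mean + spec.separation[level] * spec.sigma * u
            name = f"{path[-1]}.{i}" if path else f"L1_{i}"
            leaves.extend(offspring(child_mean, level + 1, path + (name,)))
        return leaves

    leaf_means = offspring(np.zeros(d), 0, ())
    X_rows, lineages = [], []
    for path, mean in leaf_means:
        noise = rng.standard_normal((spec.samples_per_leaf, d))
        if spec.heteroscedastic:
            sd = spec.sigma * (0.5 + 0.5 * np.abs(mean))
            X_rows.append(mean + noise * sd)
        else:
            X_rows.append(mean + noise * spec.sigma)
        lineages.extend([path] * spec.samples_per_leaf)
    X = np.vstack(X_rows)
    tree = hi.build_tree([lin for lin, _ in leaf_means])
    return X, lineages, tree


def gen_synthetic_spectra(
    classes: dict[str, list[float]],
    jitter_sigma: float = 0.002,
    noise_level: float = 1.0,
    scale_range: tuple[float, float] = (0.5, 5.0),
    replicates: int = 5,
    samples_per_class: int = 3,
    peak_sigma: float = 0.01,
    peak_amplitude: float = 1000.0,
    mz_range: tuple[float, float] = (150.0, 2000.0),
    seed: int = 0,
) -> tuple[dict[str, list[Spectrum]], dict]:
    """Generate raw profile spectra grouped by sample, plus a truth record.

    ``classes`` maps class name -> planted apex m/z positions (within the mass
    range).  Each replicate spectrum renders every planted peak as a Gaussian
    profile (width ``peak_sigma`` Da) with a per-spectrum m/z jitter, applies a
    multiplicative per-spectrum scale factor drawn log-uniformly from
    ``scale_range``, and adds a uniform noise floor of small random points.
    """
    rng = np.random.default_rng(seed)
    lo, hi = mz_range
    for cname, peaks in classes.items():
        if any(not lo <= p <= hi for p in peaks):
            raise ValueError(f"class {cname!r} has planted peaks outside {mz_range}")
    truth: dict = {"classes": {c: sorted(map(float, p)) for c, p in classes.items()},
                   "scales": {}, "samples": {}}
    out: dict[str, list[Spectrum]] = {}
    # dense profile sampling so downstream 0.001 Da binning sees no gaps
    grid_step = peak_sigma / 20.0
    for cname, peaks in classes.items():
        # class-specific amplitudes, fixed across samples/replicates
        amps = peak_amplitude * np.exp(rng.uniform(-0.5, 0.5, size=len(peaks)))
        for s in range(samples_per_class):
            sid = f"{cname}_s{s}"
            truth["samples"][sid] = cname
            out[sid] = []
            for r in range(replicates):
                scale = float(np.exp(rng.uniform(np.log(scale_range[0]),
                                                 np.log(scale_range[1]))))
                truth["scales"][f"{sid}/{r}"] = scale
                mzs, ints = [], []
                for p, a in zip(peaks, amps):
                    center = p + rng.normal(0.0, jitter_sigma) if jitter_sigma else p
                    g = np.arange(center - 4 * peak_sigma,
                                  center + 4 * peak_sigma, grid_step)
                    mzs.append(g)
                    ints.append(a * np.exp(-0.5 * ((g - center) / peak_sigma) ** 2))
                if noise_level > 0:
                    nmz = rng.uniform(lo, hi, size=200)
                    mzs.append(nmz)
                    ints.append(rng.uniform(0, noise_level, size=200))
                mz = np.concatenate(mzs)
                inten = np.concatenate(ints) * scale
                order = np.argsort(mz)
                # collapse duplicate m/z (overlapping peak grids)
                mz, inv = np.unique(mz[order], return_inverse=True)
                acc = np.zeros_like(mz)
                np.add.at(acc, inv, inten[order])
                out[sid].append(Spectrum(mz, acc, sample_id=sid, replicate=r))
    return out, truth
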