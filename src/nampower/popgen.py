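"""Descriptive population genetics: r-squared LD, LD-decay regression,
modified Rogers distance (MRD), and principal coordinate analysis (PCoA).

LD decay is summarised by fitting the drift-recombination expectation of
Hill & Weir to (distance, r^2) pairs,

    E[r^2] = ((10+C)/((2+C)(11+C))) * (1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C)))

with C = k * distance, where k (the population-recombination scale per unit
distance) is the single fitted parameter and n is the sample size.  The
fitted curve is monotone decreasing, so the distance at which expected r^2
falls to 0.1 is obtained by root bracketing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio import DistanceMatrix as _SkbioDM

from ._rng import as_rng

__all__ = [
    "r2_pair",
    "ld_pairs",
    "hill_weir_r2",
    "fit_ld_decay",
    "LdDecayFit",
    "mrd",
    "pcoa",
]


def r2_pair(dosages_a, dosages_b) -> float:
    """Squared correlation of allele dosages between two loci.

    For fully homozygous inbreds this equals the haplotype-frequency
    r^2 = D^2/(pA pB qA qB).  Missing calls (NaN) are dropped pairwise.
    Returns NaN when either locus is monomorphic among the shared calls.
    """
    a = np.asarray(dosages_a, float)
    b = np.asarray(dosages_b, float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have the same length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need >= 2 shared non-missing observations")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_pairs(
    genotypes: np.ndarray,
    gmap,
    use_cm: bool = True,
    max_pairs: int = 200_000,
    rng=None,
) -> pd.DataFrame:
    """Same-chromosome marker pairs with distances and r^2.

    For large marker sets a random subsample of at most ``max_pairs`` pairs
    is taken (seeded) to keep the decay regression desk-scale.  Monomorphic
    loci are excluded up front; pairs are intra-chromosomal only.
    """
    rng = as_rng(rng)
    g = np.asarray(genotypes, float)
    pos = gmap.pos_cm if use_cm else gmap.pos_bp.astype(float)
    records: list[tuple[int, int]] = []
    poly = np.nanstd(g, axis=0) > 0
    for sl in gmap.chrom_slices().values():
        idx = np.flatnonzero(poly[sl]) + sl.start
        if idx.size < 2:
            continue
        ii, jj = np.triu_indices(idx.size, k=1)
        records.append(np.stack([idx[ii], idx[jj]], axis=1))
    if not records:
        raise ValueError("no polymorphic same-chromosome marker pairs")
    pairs = np.concatenate(records, axis=0)
    if pairs.shape[0] > max_pairs:
        pairs = pairs[rng.choice(pairs.shape[0], size=max_pairs, replace=False)]
    i, j = pairs[:, 0], pairs[:, 1]
    # vectorised dosage correlation (no missing on the simulation path)
    if np.isnan(g).any():
        r2 = np.array([r2_pair(g[:, a], g[:, b]) for a, b in pairs])
    else:
        gc = g - g.mean(axis=0)
        sd = g.std(axis=0)
        r2 = (gc[:, i] * gc[:, j]).mean(axis=0) ** 2 / (sd[i] ** 2 * sd[j] ** 2)
    return pd.DataFrame(
        {"distance": np.abs(pos[i] - pos[j]), "r2": r2, "n": g.shape[0]}
    )


def hill_weir_r2(distance, k: float, n: float) -> np.ndarray:
    """Hill-Weir expected r^2 at C = k * distance for sample size n."""
    C = np.asarray(distance, float) * k
    a = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    b = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (n * (2.0 + C) * (11.0 + C))
    return a * b


@dataclass
class LdDecayFit:
    """Result of the LD-decay regression."""

    k: float  # recombination scale per distance unit
    n: float  # sample size used in the finite-sample term
    distance_at_r2_0_1: float  # inf (with crossed=False) if never reached
    crossed: bool

    def curve(self, distance) -> np.ndarray:
        return hill_weir_r2(distance, self.k, self.n)


def fit_ld_decay(
    distance,
    r2,
    n: float,
    threshold: float = 0.1,
    tol: float = 1e-6,
) -> LdDecayFit:
    """Nonlinear least-squares fit of the Hill-Weir decay curve.

    Parameters
    ----------
    distance, r2:
        Paired observations (same distance unit throughout — cM or bp).
    n:
        Sample size (number of lines) entering the finite-sample term.
    threshold:
        Report the distance at which the fitted curve equals this r^2.
    """
    d = np.asarray(distance, float)
    y = np.asarray(r2, float)
    ok = np.isfinite(d) & np.isfinite(y)
    d, y = d[ok], y[ok]
    if d.size < 10:
        raise ValueError("need at least 10 (distance, r2) pairs")
    scale = max(np.median(d[d > 0]), np.finfo(float).tiny)
    res = optimize.least_squares(
        lambda lk: hill_weir_r2(d, np.exp(lk[0]), n) - y,
        x0=[np.log(1.0 / scale)],
        method="lm",
    )
    if not res.success:
        raise RuntimeError(f"LD-decay fit did not converge: {res.message}")
    k = float(np.exp(res.x[0]))

    lo, hi = 0.0, scale
    if hill_weir_r2(0.0, k, n) <= threshold:
        # curve starts at/below the threshold; crossing is at the origin
        return LdDecayFit(k=k, n=n, distance_at_r2_0_1=0.0, crossed=True)
    for _ in range(200):
        if hill_weir_r2(hi, k, n) < threshold:
            break
        hi *= 2.0
    else:
        return LdDecayFit(k=k, n=n, distance_at_r2_0_1=float("inf"), crossed=False)
    x = optimize.brentq(lambda dd: hill_weir_r2(dd, k, n) - threshold, lo, hi, xtol=tol)
    return LdDecayFit(k=k, n=n, distance_at_r2_0_1=float(x), crossed=True)


def mrd(genotypes: np.ndarray, ids: list[str] | None = None) -> pd.DataFrame:
    """Modified Rogers distance between all pairs of lines.

    MRD(i,j) = sqrt( (1/2m) sum_loci sum_alleles (p_a(i) - p_a(j))^2 )
    over the m loci non-missing in both lines; for biallelic dosages this is
    sqrt( mean_loci (d_i/2 - d_j/2)^2 ).  MRD is Euclidean-embeddable, which
    makes it suitable for PCoA.
    """
    g = np.asarray(genotypes, float) / 2.0
    n = g.shape[0]
    if ids is None:
        ids = [f"L{i + 1}" for i in range(n)]
    if np.isnan(g).all(axis=1).any():
        raise ValueError("a line has no non-missing calls")
    out = np.zeros((n, n))
    miss = np.isnan(g)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            if not ok.any():
                raise ValueError(f"lines {ids[i]!r} and {ids[j]!r} share no non-missing loci")
            diff = g[i, ok] - g[j, ok]
            out[i, j] = out[j, i] = np.sqrt(np.mean(diff * diff))
    return pd.DataFrame(out, index=ids, columns=ids)


def pcoa(dist: pd.DataFrame, n_axes: int = 2, neg_tol: float = 1e-8):
    """Classical scaling of a distance matrix (delegates to scikit-bio).

    Returns ``(coordinates, proportions)``: a DataFrame of the top
    ``n_axes`` coordinates and the proportion of (positive-eigenvalue)
    variance each axis explains.  Warns if strongly negative eigenvalues
    indicate a non-Euclidean input.
    """
    vals = np.asarray(dist, float)
    if not np.allclose(vals, vals.T) or not np.allclose(np.diag(vals), 0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(_SkbioDM(vals, ids=labels), method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    if eig.min() < -neg_tol * max(eig.max(), 1.0):
        warnings.warn("strongly negative eigenvalues: distance matrix is not Euclidean")
    pos = eig > 0
    props = np.zeros_like(eig)
    props[pos] = eig[pos] / eig[pos].sum()
    k = min(n_axes, int(pos.sum()))
    coords = res.samples.iloc[:, :k].copy()
    coords.columns = [f"PCo{i + 1}" for i in range(k)]
    if labels is not None:
        coords.index = labels
    return coords, props[:k]
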