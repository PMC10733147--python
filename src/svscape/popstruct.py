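"""Population structure from SV presence/genotype matrices.

Bray-Curtis dissimilarity between individuals based on their variant
composition, principal coordinate analysis (classical metric scaling), and
the Weir & Cockerham (1984) fixation-index estimator combined as a ratio
of sums of variance components across loci.  FST is computed on a random
subset of common loci (by default 10,000 loci with cohort frequency above
10%), matching standard practice for presence-based SV matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import eigh

from .core import GenotypeMatrix

log = logging.getLogger("svscape")


def bray_curtis(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity on the binary presence matrix.

    For binary data BC(i, j) = 1 - 2*|shared| / (|vars_i| + |vars_j|).
    Samples with zero variants get dissimilarity 1 to everyone (logged).
    """
    pres = matrix.presence.astype(np.int64)
    counts = pres.sum(axis=0)
    if (counts == 0).any():
        log.warning("samples with zero variants: %s",
                    [matrix.sample_ids[i] for i in np.flatnonzero(counts == 0)])
    shared = pres.T @ pres
    denom = counts[:, None] + counts[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * shared / denom
    d[~np.isfinite(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class PCOAResult:
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent_variance: np.ndarray  # eigenvalue / sum(positive) * 100


def pcoa(d: np.ndarray, eps: float = 1e-10) -> PCOAResult:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    B = -1/2 * J D^2 J with J the centering matrix; coordinates are
    eigenvector * sqrt(eigenvalue) for positive eigenvalues.  Percent
    variance uses the sum of positive eigenvalues (Bray-Curtis is a
    semi-metric, so negative eigenvalues can occur and are excluded).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps
    if not pos.any():
        return PCOAResult(np.zeros((n, 1)), np.zeros(1), np.zeros(1))
    lam = vals[pos]
    coords = vecs[:, pos] * np.sqrt(lam)
    return PCOAResult(coords, lam, lam / lam.sum() * 100.0)


def subset_common_svs(
    matrix: GenotypeMatrix, min_freq: float = 0.10, n: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Random subset of loci with carrier frequency strictly above min_freq.

    Uniform sampling without replacement; if fewer loci qualify, all are
    returned with a warning.  Returns row indices into the matrix.
    """
    freq = matrix.carrier_counts() / len(matrix.samples)
    qualifying = np.flatnonzero(freq > min_freq)
    if qualifying.size <= n:
        if qualifying.size < n:
            log.warning("only %d loci above frequency %.2f (requested %d)",
                        qualifying.size, min_freq, n)
        return qualifying
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(qualifying, size=n, replace=False))


@dataclass
class FstResult:
    group_a: str
    group_b: str
    theta: float
    n_loci: int
    mode: str = "diploid"  # "diploid" | "haploid" (presence fallback)


def _wc84_components(dosage: np.ndarray, pops: np.ndarray) -> tuple:
    """Per-locus WC84 variance components a, b, c for two-allele diploid data.

    dosage: loci x samples with 0/1/2 and -1 missing; pops: 0/1 per sample.
    Returns (a, b, c) arrays with nan at unusable loci.
    """
    r = 2
    masks = [(pops == k) for k in range(r)]
    valid = dosage >= 0
    n_i = np.stack([(valid[:, m]).sum(axis=1) for m in masks], axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_i = np.stack(
            [
                np.where(valid[:, m], dosage[:, m], 0).sum(axis=1) / (2 * n_i[:, k])
                for k, m in enumerate(masks)
            ],
            axis=1,
        )
        h_i = np.stack(
            [
                (valid[:, m] & (dosage[:, m] == 1)).sum(axis=1) / n_i[:, k]
                for k, m in enumerate(masks)
            ],
            axis=1,
        )
    n_bar = n_i.mean(axis=1)
    n_total = n_i.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (n_total - (n_i ** 2).sum(axis=1) / n_total) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=1) / n_total
        s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=1) / n_total
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
    usable = (
        (n_i >= 2).all(axis=1)
        & (n_c > 0)
        & (p_bar > 0)
        & (p_bar < 1)
    )
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def wc_fst_pair(dosage: np.ndarray, pops: np.ndarray) -> tuple:
    """WC84 theta for one population pair: sum(a) / sum(a + b + c) over loci.

    Monomorphic or insufficiently sampled loci are skipped.  Returns
    (theta, n_loci_used).
    """
    a, b, c = _wc84_components(np.asarray(dosage), np.asarray(pops))
    ok = np.isfinite(a)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    if ok.sum() == 0 or denom == 0:
        return float("nan"), 0
    return float(np.nansum(a[ok]) / denom), int(ok.sum())


def wc_fst(
    matrix: GenotypeMatrix,
    groups: dict | None = None,
    mode: str = "diploid",
) -> list:
    """Pairwise WC84 FST between all community pairs in a GenotypeMatrix.

    ``mode="diploid"`` uses 0/1/2 dosages (missing excluded per locus);
    ``mode="haploid"`` treats the binary presence row of each sample as a
    single allele (heterozygosity 0), the fallback for presence-only input.
    """
    comms = matrix.communities
    names = sorted(set(comms))
    results = []
    for ga, gb in combinations(names, 2):
        sel = np.isin(comms, [ga, gb])
        pops = (comms[sel] == gb).astype(int)
        if mode == "diploid":
            dos = matrix.dosage[:, sel].astype(np.int16)
        elif mode == "haploid":
            # presence as one allele per individual: dosage 0/2 so p equals
            # the presence frequency and h (=dosage==1) is zero
            dos = (matrix.presence[:, sel].astype(np.int16)) * 2
        else:
            raise ValueError("mode must be 'diploid' or 'haploid'")
        theta, n_loci = wc_fst_pair(dos, pops)
        results.append(FstResult(ga, gb, theta, n_loci, mode))
    return results
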