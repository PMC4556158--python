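"""Size-aware calibration of the tetranucleotide distance into a probability.

Reference (or synthetic) genomes are shredded into fragments, random fragment
pairs are labelled intra/inter, and the empirical posterior probability that a
pair is inter-genome given its TNF Euclidean distance is approximated by a
two-parameter logistic 1/(1+exp(-(b + c*d))).  The (b, c) pair is fitted per
fragment-size pair and interpolated bilinearly in log-size, yielding a score
(TDP) in [0, 1] for contigs of arbitrary sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .tnf import tnf_matrix

__all__ = [
    "PairDistanceSample",
    "PosteriorCurve",
    "TDPModel",
    "FitError",
    "ModelBuildError",
    "shred_genomes",
    "sample_pairs",
    "empirical_posterior",
    "fit_logistic",
    "build_model",
    "default_model",
]

DEFAULT_PRIOR_RATIO = 10.0
DEFAULT_SIZE_GRID = (2500, 5000, 10000, 20000, 50000)
MIN_SIZE_CLAMP = 2500
MAX_SIZE_CLAMP = 500_000

MODEL_FORMAT_VERSION = 1


@dataclass
class PairDistanceSample:
    """TNF distances of sampled fragment pairs with sizes and intra/inter labels."""

    distances: np.ndarray
    size1: np.ndarray
    size2: np.ndarray
    inter_flag: np.ndarray


@dataclass
class PosteriorCurve:
    """Binned posterior P(inter | distance): bin centers, values, pair counts."""

    distance: np.ndarray
    posterior: np.ndarray
    weight: np.ndarray


class FitError(RuntimeError):
    """Logistic fit failed (non-convergence or non-positive slope)."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ModelBuildError(RuntimeError):
    """One or more size cells could not be fitted."""


def shred_genomes(
    genomes: list[tuple[str, str]],
    min_size: int,
    max_size: int,
    rng_seed: int,
) -> tuple[list[tuple[str, str]], int]:
    """Tile genomes into non-overlapping fragments with uniform random lengths.

    Fragment lengths are drawn uniformly on [min_size, max_size]; a trailing
    remainder shorter than min_size is discarded.  Genomes shorter than
    min_size are skipped; the count of skipped genomes is returned alongside
    the labelled fragments.
    """
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    rng = np.random.default_rng(rng_seed)
    fragments: list[tuple[str, str]] = []
    n_skipped = 0
    for label, seq in genomes:
        n = len(seq)
        if n < min_size:
            n_skipped += 1
            continue
        pos = 0
        while n - pos >= min_size:
            length = int(rng.integers(min_size, max_size + 1))
            length = min(length, n - pos)
            fragments.append((label, seq[pos : pos + length]))
            pos += length
    return fragments, n_skipped


def sample_pairs(
    fragments: list[tuple[str, str]],
    n_pairs: int,
    rng_seed: int,
) -> PairDistanceSample:
    """Draw random distinct fragment pairs (with replacement over pairs).

    Records the TNF Euclidean distance, both fragment sizes and whether the
    fragments carry different genome labels.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments to sample pairs")
    labels = np.array([lab for lab, _ in fragments])
    sizes = np.array([len(seq) for _, seq in fragments])
    mat, valid = tnf_matrix([seq for _, seq in fragments])
    if np.any(valid < 1):
        raise ValueError("fragment with no valid 4-mers cannot enter pair sampling")
    rng = np.random.default_rng(rng_seed)
    i = rng.integers(0, len(fragments), size=n_pairs)
    j = rng.integers(0, len(fragments), size=n_pairs)
    clash = i == j
    while np.any(clash):
        j[clash] = rng.integers(0, len(fragments), size=int(clash.sum()))
        clash = i == j
    d = np.linalg.norm(mat[i] - mat[j], axis=1)
    return PairDistanceSample(d, sizes[i], sizes[j], labels[i] != labels[j])


def _cross_sample_pairs(
    mat1: np.ndarray,
    labels1: np.ndarray,
    sizes1: np.ndarray,
    mat2: np.ndarray,
    labels2: np.ndarray,
    sizes2: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
) -> PairDistanceSample:
    """Pairs with one fragment from each of two (disjoint) fragment pools."""
    i = rng.integers(0, len(labels1), size=n_pairs)
    j = rng.integers(0, len(labels2), size=n_pairs)
    d = np.linalg.norm(mat1[i] - mat2[j], axis=1)
    return PairDistanceSample(d, sizes1[i], sizes2[j], labels1[i] != labels2[j])


def empirical_posterior(
    sample: PairDistanceSample,
    prior_ratio: float = DEFAULT_PRIOR_RATIO,
    n_bins: int = 100,
) -> PosteriorCurve:
    """Histogram posterior P(inter | distance bin) with prior ratio P(T)/P(R).

    Class-conditional densities are equal-width histograms over the observed
    distance range; the posterior per bin is r*f_T / (r*f_T + f_R).  Bins with
    no mass in either class are dropped.
    """
    if prior_ratio <= 0:
        raise ValueError("prior_ratio must be positive")
    inter = sample.inter_flag.astype(bool)
    d_t = sample.distances[inter]
    d_r = sample.distances[~inter]
    if d_t.size == 0 or d_r.size == 0:
        raise ValueError("sample must contain both intra and inter pairs")
    lo = float(sample.distances.min())
    hi = float(sample.distances.max())
    if hi <= lo:
        raise ValueError("all sampled distances are identical; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    cnt_t, _ = np.histogram(d_t, bins=edges)
    cnt_r, _ = np.histogram(d_r, bins=edges)
    # equal-width bins: densities are proportional to class fractions
    f_t = cnt_t / d_t.size
    f_r = cnt_r / d_r.size
    keep = (cnt_t + cnt_r) > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    num = prior_ratio * f_t[keep]
    post = num / (num + f_r[keep])
    return PosteriorCurve(centers[keep], post, (cnt_t + cnt_r)[keep].astype(float))


def fit_logistic(
    distance: np.ndarray,
    posterior: np.ndarray,
    weight: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> tuple[float, float]:
    """Weighted ML fit of p = 1/(1+exp(-(b + c*d))) by damped Newton iteration.

    ``posterior`` holds per-bin proportions in [0,1], ``weight`` the per-bin
    pair counts.  Raises :class:`FitError` on non-convergence or when the
    fitted slope c is not positive.  A small ``ridge`` penalty stabilises
    perfectly separated curves.
    """
    d = np.asarray(distance, dtype=float)
    p = np.asarray(posterior, dtype=float)
    w = np.ones_like(d) if weight is None else np.asarray(weight, dtype=float)
    if d.size < 3 or np.unique(d).size < 3:
        raise FitError("need at least 3 distinct distance bins")
    if np.ptp(p) == 0:
        raise FitError("posterior curve is constant; logistic is unidentifiable")

    X = np.column_stack([np.ones_like(d), d])

    def negll(theta: np.ndarray) -> float:
        eta = X @ theta
        # log(1+exp(eta)) computed stably
        softplus = np.logaddexp(0.0, eta)
        val = float(np.sum(w * (softplus - p * eta)))
        return val + 0.5 * ridge * float(theta @ theta)

    # init from weighted least squares on clipped logits
    pc = np.clip(p, 1e-9, 1 - 1e-9)
    y = np.log(pc / (1 - pc))
    sw = np.sqrt(w)
    theta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)

    converged = False
    for _ in range(max_iter):
        eta = X @ theta
        q = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (q - p)) + ridge * theta
        h = q * (1 - q)
        H = (X * (w * h)[:, None]).T @ X + ridge * np.eye(2)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # singular Hessian
            raise FitError("singular Hessian in logistic fit", {"theta": theta.tolist()}) from exc
        f0 = negll(theta)
        scale = 1.0
        for _ in range(40):
            cand = theta - scale * step
            if negll(cand) <= f0 + 1e-15:
                break
            scale *= 0.5
        theta = theta - scale * step
        if np.max(np.abs(scale * step)) < tol * (1.0 + np.max(np.abs(theta))):
            converged = True
            break
    if not converged:
        raise FitError(
            "logistic fit did not converge",
            {"theta": theta.tolist(), "max_iter": max_iter},
        )
    b, c = float(theta[0]), float(theta[1])
    if c <= 0:
        raise FitError(f"fitted slope must be positive, got c={c:.4g}", {"b": b, "c": c})
    return b, c


@dataclass
class TDPModel:
    """Fitted logistic parameter surfaces over a fragment-size grid."""

    size_grid: np.ndarray
    b_surface: np.ndarray
    c_surface: np.ndarray
    prior_ratio: float = DEFAULT_PRIOR_RATIO
    min_size_clamp: int = MIN_SIZE_CLAMP
    max_size_clamp: int = MAX_SIZE_CLAMP
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.size_grid = np.asarray(self.size_grid, dtype=float)
        self.b_surface = np.asarray(self.b_surface, dtype=float)
        self.c_surface = np.asarray(self.c_surface, dtype=float)

    def _interp_params(self, len1, len2) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear interpolation of (b, c) in log-size coordinates."""
        g = np.log(self.size_grid)
        out = []
        xs = []
        for lens in (len1, len2):
            L = np.clip(np.asarray(lens, dtype=float), self.min_size_clamp, self.max_size_clamp)
            x = np.log(np.clip(L, self.size_grid[0], self.size_grid[-1]))
            xs.append(x)
        idx = []
        frac = []
        for x in xs:
            i = np.clip(np.searchsorted(g, x, side="right") - 1, 0, len(g) - 2)
            t = (x - g[i]) / (g[i + 1] - g[i])
            idx.append(i)
            frac.append(np.clip(t, 0.0, 1.0))
        i1, i2 = idx
        t1, t2 = frac
        for surf in (self.b_surface, self.c_surface):
            v = (
                (1 - t1) * (1 - t2) * surf[i1, i2]
                + t1 * (1 - t2) * surf[i1 + 1, i2]
                + (1 - t1) * t2 * surf[i1, i2 + 1]
                + t1 * t2 * surf[i1 + 1, i2 + 1]
            )
            out.append(v)
        return out[0], out[1]

    def tdp(self, d, len1, len2):
        """Probability the pair is inter-genome given TNF distance and sizes."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("TNF distance must be non-negative")
        b, c = self._interp_params(len1, len2)
        val = 1.0 / (1.0 + np.exp(-(b + c * d)))
        return float(val) if val.ndim == 0 else val

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "size_grid": self.size_grid.tolist(),
            "b_surface": self.b_surface.tolist(),
            "c_surface": self.c_surface.tolist(),
            "prior_ratio": self.prior_ratio,
            "min_size_clamp": self.min_size_clamp,
            "max_size_clamp": self.max_size_clamp,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TDPModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version in {path}")
        return cls(
            size_grid=np.array(payload["size_grid"]),
            b_surface=np.array(payload["b_surface"]),
            c_surface=np.array(payload["c_surface"]),
            prior_ratio=payload["prior_ratio"],
            min_size_clamp=payload["min_size_clamp"],
            max_size_clamp=payload["max_size_clamp"],
            metadata=payload.get("metadata", {}),
        )


def build_model(
    genomes: list[tuple[str, str]],
    size_grid: tuple[int, ...] = DEFAULT_SIZE_GRID,
    pairs_per_cell: int = 10_000,
    prior_ratio: float = DEFAULT_PRIOR_RATIO,
    rng_seed: int = 0,
    n_bins: int = 100,
) -> TDPModel:
    """Train logistic (b, c) surfaces by shredding genomes at each grid size.

    For every unordered size pair the genomes are shredded at the two fixed
    sizes, pairs are sampled across the two fragment pools, the binned
    posterior is computed and the logistic fitted.  Cells whose plain ML fit
    diverges (perfectly separated curves) are refitted with a small ridge
    penalty; cells failing both ways abort the build.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes to train a TDP model")
    size_grid = tuple(int(s) for s in size_grid)
    if size_grid != tuple(sorted(size_grid)):
        raise ValueError("size_grid must be ascending")
    if size_grid[0] < MIN_SIZE_CLAMP or size_grid[-1] > MAX_SIZE_CLAMP:
        raise ValueError(f"size_grid must lie within [{MIN_SIZE_CLAMP}, {MAX_SIZE_CLAMP}]")

    ss = np.random.SeedSequence(rng_seed)
    shred_seeds = ss.spawn(len(size_grid))
    pools = {}
    for s, child in zip(size_grid, shred_seeds):
        frags, _ = shred_genomes(genomes, s, s, int(child.generate_state(1)[0]))
        labels = np.array([lab for lab, _ in frags])
        if len(frags) < 2 or np.unique(labels).size < 2:
            raise ModelBuildError(f"not enough fragments at size {s} to sample pairs")
        mat, _ = tnf_matrix([seq for _, seq in frags])
        pools[s] = (mat, labels, np.array([len(seq) for _, seq in frags]))

    n = len(size_grid)
    b_surf = np.zeros((n, n))
    c_surf = np.zeros((n, n))
    failures = []
    pair_rng = np.random.default_rng(ss.spawn(1)[0])
    for i in range(n):
        for j in range(i, n):
            si, sj = size_grid[i], size_grid[j]
            m1, l1, z1 = pools[si]
            m2, l2, z2 = pools[sj]
            sample = _cross_sample_pairs(m1, l1, z1, m2, l2, z2, pairs_per_cell, pair_rng)
            try:
                curve = empirical_posterior(sample, prior_ratio, n_bins)
                try:
                    b, c = fit_logistic(curve.distance, curve.posterior, curve.weight)
                except FitError:
                    b, c = fit_logistic(
                        curve.distance, curve.posterior, curve.weight, ridge=1e-6
                    )
            except (FitError, ValueError) as exc:
                failures.append((si, sj, str(exc)))
                continue
            b_surf[i, j] = b_surf[j, i] = b
            c_surf[i, j] = c_surf[j, i] = c
    if failures:
        detail = "; ".join(f"({si},{sj}): {msg}" for si, sj, msg in failures)
        raise ModelBuildError(f"logistic fit failed for cells {detail}")
    return TDPModel(
        size_grid=np.array(size_grid, dtype=float),
        b_surface=b_surf,
        c_surface=c_surf,
        prior_ratio=prior_ratio,
        metadata={
            "n_genomes": len(genomes),
            "pairs_per_cell": pairs_per_cell,
            "n_bins": n_bins,
            "rng_seed": rng_seed,
        },
    )


def default_model(rng_seed: int = 7, pairs_per_cell: int = 10_000) -> TDPModel:
    """Train the bundled default model on synthetic Markov-chain genomes."""
    from .synthetic import generate_genome

    ss = np.random.SeedSequence([rng_seed, 101])
    genomes = [
        (f"train{k}", generate_genome(2, 3.0, 1_000_000, int(child.generate_state(1)[0])))
        for k, child in enumerate(ss.spawn(6))
    ]
    model = build_model(genomes, rng_seed=rng_seed, pairs_per_cell=pairs_per_cell)
    model.metadata["training"] = "synthetic order-2 Markov genomes"
    return model
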