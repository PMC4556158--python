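"""Per-sample coverage profiles and the abundance distance probability (ADP).

The per-sample abundance distance of two contigs is the non-shared area of the
two normal distributions inferred from their (mean, variance) base depths —
i.e. the total-variation distance, evaluated in closed form from normal CDFs
at the crossing points of the two densities.  Per-sample distances are
combined as a geometric mean over "informative" samples (those where at least
one contig exceeds a minimum abundance), and the composite layer weights the
result by w = min(log(n+1)/log(m+1), alpha) with n the informative-sample
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import ndtr

__all__ = [
    "CoverageProfile",
    "AbundanceConfig",
    "read_depth_table",
    "write_depth_table",
    "depths_from_bam",
    "adp_single",
    "adp_single_vec",
    "adp_combined",
    "abundance_weight",
]


@dataclass(frozen=True)
class CoverageProfile:
    """Mean base depth and depth variance of one contig in each sample."""

    contig_id: str
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "variances", np.asarray(self.variances, dtype=float))
        if self.means.shape != self.variances.shape:
            raise ValueError(f"{self.contig_id}: means and variances differ in length")
        if np.any(self.means < 0) or np.any(self.variances < 0):
            raise ValueError(f"{self.contig_id}: negative depth mean or variance")

    @property
    def n_samples(self) -> int:
        return self.means.size


@dataclass(frozen=True)
class AbundanceConfig:
    """Knobs of the abundance distance.

    min_cv: minimum mean depth for a sample to count as informative.
    variance_floor: substitute for zero reported variances.
    weight_m / weight_alpha: parameters of the ADP weight
    min(log(n+1)/log(m+1), alpha).
    """

    min_cv: float = 1.0
    variance_floor: float = 1e-4
    weight_m: int = 100
    weight_alpha: float = 0.9

    def __post_init__(self):
        if not (0 < self.weight_alpha <= 1):
            raise ValueError("weight_alpha must be in (0, 1]")
        if self.weight_m < 1:
            raise ValueError("weight_m must be >= 1")
        if self.min_cv < 0:
            raise ValueError("min_cv must be >= 0")


DEPTH_TABLE_COLUMNS = ("contigName", "contigLen", "totalAvgDepth")


def read_depth_table(path: str | Path) -> list[CoverageProfile]:
    """Parse a JGI-style depth table.

    Header: contigName, contigLen, totalAvgDepth, then one (mean, variance)
    column pair per sample.  totalAvgDepth is read but not used for distance
    math.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or tuple(header[:3]) != DEPTH_TABLE_COLUMNS:
            raise ValueError(
                f"{path}: depth table must start with columns {DEPTH_TABLE_COLUMNS}"
            )
        n_extra = len(header) - 3
        if n_extra % 2 != 0:
            raise ValueError(
                f"{path}: expected per-sample (mean, variance) column pairs, "
                f"got {n_extra} extra columns"
            )
        n_samples = n_extra // 2
        profiles: list[CoverageProfile] = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ValueError(f"{path}: row {lineno} has {len(cells)} columns, "
                                 f"expected {len(header)}")
            try:
                vals = [float(x) for x in cells[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell at row {lineno}") from exc
            means = np.array(vals[2::2][:n_samples])
            variances = np.array(vals[3::2][:n_samples])
            profiles.append(CoverageProfile(cells[0], means, variances))
    return profiles


def write_depth_table(
    path: str | Path,
    profiles: list[CoverageProfile],
    lengths: dict[str, int],
    sample_names: list[str] | None = None,
) -> None:
    """Write profiles in the depth-table layout accepted by read_depth_table."""
    if not profiles:
        raise ValueError("no profiles to write")
    n = profiles[0].n_samples
    names = sample_names or [f"sample{k + 1}.bam" for k in range(n)]
    with open(path, "w") as fh:
        cols = list(DEPTH_TABLE_COLUMNS)
        for name in names:
            cols += [name, f"{name}-var"]
        fh.write("\t".join(cols) + "\n")
        for p in profiles:
            total = float(p.means.mean()) if n else 0.0
            row = [p.contig_id, str(lengths[p.contig_id]), f"{total:.6f}"]
            for m, v in zip(p.means, p.variances):
                row += [f"{m:.6f}", f"{v:.6f}"]
            fh.write("\t".join(row) + "\n")


def _keep_read(read) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_duplicate
        or read.is_supplementary
    )


def depths_from_bam(bam_paths: list[str | Path], contigs) -> list[CoverageProfile]:
    """Per-contig depth mean/variance from sorted, indexed BAM files.

    Depth counts primary, non-duplicate, non-supplementary alignments at
    every contig position (zero-depth positions included); the variance is
    the population variance.  A contig missing from any BAM header is a hard
    error because it indicates an assembly/alignment mismatch.
    """
    import pysam

    n_samples = len(bam_paths)
    ids = [c.id for c in contigs]
    lengths = {c.id: c.length for c in contigs}
    means = {cid: np.zeros(n_samples) for cid in ids}
    variances = {cid: np.zeros(n_samples) for cid in ids}
    for s, bam_path in enumerate(bam_paths):
        with pysam.AlignmentFile(str(bam_path), "rb") as bam:
            if not bam.has_index():
                raise ValueError(f"{bam_path}: BAM file must be indexed")
            refs = set(bam.references)
            for cid in ids:
                if cid not in refs:
                    raise ValueError(
                        f"{bam_path}: contig {cid!r} absent from BAM header "
                        "(assembly/alignment mismatch)"
                    )
                cov = bam.count_coverage(
                    cid, 0, lengths[cid], quality_threshold=0, read_callback=_keep_read
                )
                depth = np.asarray(cov, dtype=float).sum(axis=0)
                means[cid][s] = depth.mean()
                variances[cid][s] = depth.var()  # population variance
    return [CoverageProfile(cid, means[cid], variances[cid]) for cid in ids]


def adp_single_vec(mu1, var1, mu2, var2, variance_floor: float = 1e-4) -> np.ndarray:
    """Vectorized non-shared area of two normal distributions.

    Equal-variance pairs use Phi_1(k0) - Phi_2(k0) at the midpoint k0; the
    general case evaluates the CDF difference at the two density crossing
    points with sigma2 >= sigma1 enforced by swapping.  Output is clipped to
    [0, 1].
    """
    mu1 = np.asarray(mu1, dtype=float)
    var1 = np.asarray(var1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    var2 = np.asarray(var2, dtype=float)
    mu1, var1, mu2, var2 = np.broadcast_arrays(mu1, var1, mu2, var2)
    if not (np.all(np.isfinite(mu1)) and np.all(np.isfinite(var1))
            and np.all(np.isfinite(mu2)) and np.all(np.isfinite(var2))):
        raise ValueError("non-finite abundance parameters")
    v1 = np.maximum(var1, variance_floor)
    v2 = np.maximum(var2, variance_floor)

    # enforce var2 >= var1
    swap = v1 > v2
    m1 = np.where(swap, mu2, mu1)
    m2 = np.where(swap, mu1, mu2)
    a1 = np.where(swap, v2, v1)
    a2 = np.where(swap, v1, v2)

    s1 = np.sqrt(a1)
    s2 = np.sqrt(a2)
    dmu = m2 - m1

    equal = np.abs(a2 - a1) <= 1e-12 * a2
    # equal-variance branch: 2*Phi(|dmu|/(2*sigma)) - 1
    res_eq = 2.0 * ndtr(np.abs(dmu) / (2.0 * s1)) - 1.0

    denom = np.where(equal, 1.0, a1 - a2)  # placeholder denom where equal
    disc = a1 * a2 * (dmu**2 - 2.0 * (a1 - a2) * np.log(s2 / np.where(equal, s2, s1)))
    root = np.sqrt(np.maximum(disc, 0.0))
    k1s = (root - m1 * a2 + m2 * a1) / denom
    k2s = (-root - m1 * a2 + m2 * a1) / denom
    k1 = np.minimum(k1s, k2s)
    k2 = np.maximum(k1s, k2s)
    res_gen = np.abs(
        ndtr((k2 - m1) / s1)
        - ndtr((k1 - m1) / s1)
        + ndtr((k1 - m2) / s2)
        - ndtr((k2 - m2) / s2)
    )
    res = np.where(equal | ~np.isfinite(res_gen), res_eq, res_gen)
    # identical parameter pairs (after flooring) have zero distance exactly
    res = np.where((dmu == 0) & (a1 == a2), 0.0, res)
    return np.clip(res, 0.0, 1.0)


def adp_single(
    mu1: float, var1: float, mu2: float, var2: float, variance_floor: float = 1e-4
) -> float:
    """Scalar non-shared area (total-variation distance) of two normals."""
    for x in (mu1, var1, mu2, var2):
        if not math.isfinite(x):
            raise ValueError("non-finite abundance parameters")
    return float(adp_single_vec(mu1, var1, mu2, var2, variance_floor))


def adp_combined(
    p1: CoverageProfile, p2: CoverageProfile, cfg: AbundanceConfig = AbundanceConfig()
) -> tuple[float, int]:
    """Geometric mean of per-sample distances over informative samples.

    A sample is informative when either contig's mean depth exceeds
    ``cfg.min_cv``.  Returns (nan, 0) when no sample is informative; the
    composite layer then falls back to TDP alone.
    """
    if p1.n_samples != p2.n_samples:
        raise ValueError("profiles cover different numbers of samples")
    informative = (p1.means > cfg.min_cv) | (p2.means > cfg.min_cv)
    n_inf = int(informative.sum())
    if n_inf == 0:
        return float("nan"), 0
    p = adp_single_vec(
        p1.means[informative],
        p1.variances[informative],
        p2.means[informative],
        p2.variances[informative],
        cfg.variance_floor,
    )
    with np.errstate(divide="ignore"):
        logs = np.log(p)
    gm = float(np.exp(logs.mean())) if np.all(np.isfinite(logs)) else 0.0
    return gm, n_inf


def abundance_weight(n_samples: int, cfg: AbundanceConfig = AbundanceConfig()) -> float:
    """ADP weight w = min(log(n+1)/log(m+1), alpha); n is the informative count."""
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    return min(math.log(n_samples + 1) / math.log(cfg.weight_m + 1), cfg.weight_alpha)
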