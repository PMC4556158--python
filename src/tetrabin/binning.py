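"""Iterative medoid clustering of contigs over the composite distance.

One bin at a time: seed on the highest-coverage unbinned contig, recruit
everything within the cutoff distance 1-p1 of the current medoid, re-pick the
medoid, and repeat until the medoid is stable; optionally tighten membership
to 1-p2 afterwards.  The sweep continues until no contig is left, then bins
at or below the minimum size are dissolved.  With enough samples, leftover
contigs can be recruited into retained bins by depth-profile correlation.

All tie-breaks are total orders on (criterion, length, id) so runs are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .abundance import CoverageProfile
from .tnf import ContigRecord

__all__ = [
    "Bin",
    "BinningConfig",
    "select_seed",
    "form_bin",
    "bin_all",
    "recruit_small_contigs",
    "write_bins",
]

logger = logging.getLogger(__name__)


@dataclass
class Bin:
    bin_id: int
    member_ids: set[str]
    medoid_id: str
    total_bases: int


@dataclass(frozen=True)
class BinningConfig:
    """Clustering knobs; p1/p2 are probability cutoffs applied as distance
    cutoffs 1-p1 (recruitment) and 1-p2 (post-convergence refinement)."""

    p1: float = 0.90
    p2: float = 0.95
    min_contig_size: int = 2500
    min_bin_size: int = 200_000
    min_samples_for_recruit: int = 10
    recruit_corr: float = 0.9
    max_medoid_iters: int = 50
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.p1 <= self.p2 < 1):
            raise ValueError("require 0 < p1 <= p2 < 1")
        if self.min_contig_size < 1500:
            raise ValueError("min_contig_size must be >= 1500")
        if self.min_bin_size <= 0:
            raise ValueError("min_bin_size must be positive")


def select_seed(
    unbinned: set[str],
    profiles: dict[str, CoverageProfile] | None,
    lengths: dict[str, int] | None = None,
) -> str:
    """Unbinned contig with the greatest summed mean depth across samples.

    Ties go to the longer contig, then the lexicographically smaller id.
    Without coverage (TNF-only mode) the longest contig seeds.
    """
    if not unbinned:
        raise RuntimeError("cannot select a seed from an empty contig set")
    lengths = lengths or {}

    def key(cid: str):
        depth = float(profiles[cid].means.sum()) if profiles else 0.0
        return (-depth, -lengths.get(cid, 0), cid)

    return min(unbinned, key=key)


def form_bin(seed: str, candidates: set[str], distances, cfg: BinningConfig) -> Bin:
    """Grow one bin from a seed by alternating recruitment and medoid update.

    Recruitment collects candidates within 1-p1 of the current medoid; the
    new medoid is the member with the smallest summed distance over the
    candidate pool (ties: longer contig, then smaller id).  After the medoid
    stabilises, members farther than 1-p2 from it are dropped when p2 > p1.
    """
    if seed not in candidates:
        raise ValueError("seed must be among the candidates")
    cand_ids = sorted(candidates)
    idx = np.array([distances.index_of(c) for c in cand_ids], dtype=np.int64)
    pos_of = {c: k for k, c in enumerate(cand_ids)}
    lengths = {c: int(distances.lengths[distances.index_of(c)]) for c in cand_ids}

    cutoff = 1.0 - cfg.p1
    medoid = seed
    member_pos = None
    sums_cache: dict[str, float] = {}

    def summed_distance(cid: str) -> float:
        if cid not in sums_cache:
            sums_cache[cid] = float(distances.rows(distances.index_of(cid), idx).sum())
        return sums_cache[cid]

    for _ in range(cfg.max_medoid_iters):
        row = distances.rows(distances.index_of(medoid), idx)
        member_pos = np.where(row <= cutoff)[0]
        if pos_of[medoid] not in member_pos:
            member_pos = np.append(member_pos, pos_of[medoid])
        best = min(
            (cand_ids[p] for p in member_pos),
            key=lambda cid: (summed_distance(cid), -lengths[cid], cid),
        )
        if best == medoid:
            break
        medoid = best

    row = distances.rows(distances.index_of(medoid), idx)
    members = {cand_ids[p] for p in np.where(row <= cutoff)[0]} | {medoid}
    if cfg.p2 > cfg.p1:
        tight = 1.0 - cfg.p2
        members = {c for c in members if row[pos_of[c]] <= tight} | {medoid}
    total = sum(lengths[c] for c in members)
    return Bin(bin_id=0, member_ids=members, medoid_id=medoid, total_bases=total)


def bin_all(
    contigs: list[ContigRecord],
    distances,
    profiles: dict[str, CoverageProfile] | None,
    cfg: BinningConfig,
) -> tuple[list[Bin], set[str]]:
    """Single-sweep exhaustive binning followed by small-bin dissolution.

    Bins whose total bases do not exceed ``cfg.min_bin_size`` are dissolved
    into the free pool (their members are not re-seeded); retained bins are
    renumbered 1..k by descending total bases.
    """
    if not contigs:
        return [], set()
    lengths = {c.id: c.length for c in contigs}
    unbinned = set(lengths)
    raw_bins: list[Bin] = []
    while unbinned:
        seed = select_seed(unbinned, profiles, lengths)
        b = form_bin(seed, unbinned, distances, cfg)
        raw_bins.append(b)
        unbinned -= b.member_ids
    retained = [b for b in raw_bins if b.total_bases > cfg.min_bin_size]
    free: set[str] = set()
    for b in raw_bins:
        if b.total_bases <= cfg.min_bin_size:
            free |= b.member_ids
    order = sorted(range(len(retained)), key=lambda k: (-retained[k].total_bases, k))
    bins = []
    for rank, k in enumerate(order, start=1):
        b = retained[k]
        bins.append(Bin(rank, b.member_ids, b.medoid_id, b.total_bases))
    return bins, free


def recruit_small_contigs(
    bins: list[Bin],
    small_contigs: list[ContigRecord],
    profiles: dict[str, CoverageProfile],
    cfg: BinningConfig,
) -> list[Bin]:
    """Assign leftover contigs to bins by Pearson depth-profile correlation.

    Requires at least ``cfg.min_samples_for_recruit`` samples, otherwise a
    no-op.  A contig joins the bin with the highest correlation when that
    correlation reaches ``cfg.recruit_corr`` and strictly beats the
    runner-up; ties leave the contig unassigned.
    """
    if not bins or not small_contigs:
        return bins
    n_samples = next(iter(profiles.values())).n_samples
    if n_samples < cfg.min_samples_for_recruit:
        logger.info(
            "correlation recruitment skipped: %d samples < %d required",
            n_samples,
            cfg.min_samples_for_recruit,
        )
        return bins

    bin_profiles = []
    for b in bins:
        member_means = np.stack([profiles[cid].means for cid in sorted(b.member_ids)])
        bin_profiles.append(member_means.mean(axis=0))

    def correlation(x: np.ndarray, y: np.ndarray) -> float:
        if x.std() == 0 or y.std() == 0:
            return float("-inf")
        return float(np.corrcoef(x, y)[0, 1])

    updated = [Bin(b.bin_id, set(b.member_ids), b.medoid_id, b.total_bases) for b in bins]
    for contig in sorted(small_contigs, key=lambda c: c.id):
        if contig.id not in profiles:
            continue
        vec = profiles[contig.id].means
        rs = np.array([correlation(vec, bp) for bp in bin_profiles])
        best = int(np.argmax(rs))
        runner_up = float(np.max(np.delete(rs, best))) if len(rs) > 1 else float("-inf")
        if rs[best] >= cfg.recruit_corr and rs[best] > runner_up:
            updated[best].member_ids.add(contig.id)
            updated[best].total_bases += contig.length
    return updated


def write_bins(
    bins: list[Bin],
    contigs: list[ContigRecord],
    outdir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write one FASTA per bin plus membership and summary tables.

    membership.tsv holds one row per input contig (bin_id 0 = unbinned);
    summary.tsv holds (bin_id, n_contigs, total_bases, medoid_id).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    paths = [outdir / f"bin.{b.bin_id}.fa" for b in bins]
    paths += [outdir / "membership.tsv", outdir / "summary.tsv"]
    if not overwrite:
        clashes = [p for p in paths if p.exists()]
        if clashes:
            raise FileExistsError(f"output files exist (use overwrite): {clashes[:3]}")

    bin_of: dict[str, int] = {}
    for b in bins:
        for cid in b.member_ids:
            bin_of[cid] = b.bin_id
    by_id = {c.id: c for c in contigs}
    for b in bins:
        path = outdir / f"bin.{b.bin_id}.fa"
        with open(path, "w") as fh:
            for c in contigs:
                if c.id in b.member_ids:
                    fh.write(f">{c.id}\n")
                    for k in range(0, c.length, 80):
                        fh.write(c.sequence[k : k + 80] + "\n")
        manifest[f"bin.{b.bin_id}.fa"] = path

    mpath = outdir / "membership.tsv"
    with open(mpath, "w") as fh:
        fh.write("contig_id\tbin_id\n")
        for c in contigs:
            fh.write(f"{c.id}\t{bin_of.get(c.id, 0)}\n")
    manifest["membership.tsv"] = mpath

    spath = outdir / "summary.tsv"
    with open(spath, "w") as fh:
        fh.write("bin_id\tn_contigs\ttotal_bases\tmedoid_id\n")
        for b in bins:
            total = sum(by_id[cid].length for cid in b.member_ids)
            if total != b.total_bases:
                raise AssertionError(f"bin {b.bin_id}: base-count mismatch")
            fh.write(f"{b.bin_id}\t{len(b.member_ids)}\t{b.total_bases}\t{b.medoid_id}\n")
    manifest["summary.tsv"] = spath
    return manifest
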