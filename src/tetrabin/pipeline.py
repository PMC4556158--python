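"""End-to-end binning pipeline shared by the CLI and the test suite."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .abundance import AbundanceConfig, CoverageProfile
from .binning import BinningConfig, bin_all, recruit_small_contigs, write_bins
from .composite import DEFAULT_TDP_SWITCH, CompositeDistanceProvider
from .tdp import TDPModel, default_model
from .tnf import ContigRecord, tnf_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_binning"]


@dataclass
class PipelineResult:
    bins: list
    free: set[str]
    contigs: list[ContigRecord]
    small_contigs: list[ContigRecord]
    manifest: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _ids_digest(ids: list[str]) -> str:
    h = hashlib.sha256()
    for cid in ids:
        h.update(cid.encode())
        h.update(b"\0")
    return h.hexdigest()


def _cached_tnf(contigs: list[ContigRecord], cache_dir: Path | None) -> np.ndarray:
    """TNF matrix for the contig set, reusing a cache keyed by the id list."""
    ids = [c.id for c in contigs]
    if cache_dir is None:
        return tnf_matrix([c.sequence for c in contigs])[0]
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _ids_digest(ids)
    npy = cache_dir / "tnf.npy"
    meta = cache_dir / "tnf.json"
    if npy.exists() and meta.exists():
        try:
            if json.loads(meta.read_text()).get("digest") == key:
                logger.info("reusing cached TNF matrix from %s", npy)
                return np.load(npy)
        except (ValueError, OSError):
            pass
    mat, _ = tnf_matrix([c.sequence for c in contigs])
    np.save(npy, mat)
    meta.write_text(json.dumps({"digest": key, "n": len(ids)}))
    return mat


def run_binning(
    contigs: list[ContigRecord],
    profiles: list[CoverageProfile] | None,
    outdir: str | Path,
    model: TDPModel | None = None,
    bin_cfg: BinningConfig = BinningConfig(),
    ab_cfg: AbundanceConfig = AbundanceConfig(),
    tdp_switch: float = DEFAULT_TDP_SWITCH,
    cache_dir: str | Path | None = None,
    overwrite: bool = False,
    write_outputs: bool = True,
) -> PipelineResult:
    """Filter, score, cluster and (optionally) write bins for one assembly."""
    outdir = Path(outdir)
    cache_dir = Path(cache_dir) if cache_dir is not None else None
    if model is None:
        model = _cached_default_model(cache_dir, bin_cfg.rng_seed)

    large = [c for c in contigs if c.length >= bin_cfg.min_contig_size]
    small = [c for c in contigs if c.length < bin_cfg.min_contig_size]
    if not large:
        raise ValueError(
            f"no contigs of at least {bin_cfg.min_contig_size} bases to bin"
        )
    prof_by_id = None
    means = variances = None
    n_samples = 0
    if profiles is not None:
        prof_by_id = {p.contig_id: p for p in profiles}
        missing = [c.id for c in large if c.id not in prof_by_id]
        if missing:
            raise ValueError(f"coverage missing for contigs: {missing[:5]}")
        means = np.stack([prof_by_id[c.id].means for c in large])
        variances = np.stack([prof_by_id[c.id].variances for c in large])
        n_samples = means.shape[1]

    tnf_values = _cached_tnf(large, cache_dir)
    provider = CompositeDistanceProvider(
        [c.id for c in large],
        np.array([c.length for c in large], dtype=np.int64),
        tnf_values,
        model,
        means,
        variances,
        ab_cfg,
        tdp_switch,
    )
    distances = provider.dense() if len(large) <= 20_000 else provider
    bins, free = bin_all(large, distances, prof_by_id, bin_cfg)
    if prof_by_id is not None and n_samples >= bin_cfg.min_samples_for_recruit:
        leftovers = [c for c in contigs if c.id in free or c.length < bin_cfg.min_contig_size]
        leftovers = [c for c in leftovers if c.id in prof_by_id]
        bins = recruit_small_contigs(bins, leftovers, prof_by_id, bin_cfg)
        binned = set().union(*(b.member_ids for b in bins)) if bins else set()
        free = {c.id for c in contigs if c.id not in binned}

    result = PipelineResult(bins=bins, free=free, contigs=contigs, small_contigs=small)
    result.report = {
        "version": __version__,
        "n_contigs_input": len(contigs),
        "n_contigs_binned_pool": len(large),
        "n_contigs_small": len(small),
        "n_samples": n_samples,
        "n_bins": len(bins),
        "n_free": len(free),
        "config": {
            "p1": bin_cfg.p1,
            "p2": bin_cfg.p2,
            "min_contig_size": bin_cfg.min_contig_size,
            "min_bin_size": bin_cfg.min_bin_size,
            "min_samples_for_recruit": bin_cfg.min_samples_for_recruit,
            "recruit_corr": bin_cfg.recruit_corr,
            "rng_seed": bin_cfg.rng_seed,
            "min_cv": ab_cfg.min_cv,
            "variance_floor": ab_cfg.variance_floor,
            "weight_m": ab_cfg.weight_m,
            "weight_alpha": ab_cfg.weight_alpha,
            "tdp_switch": tdp_switch,
        },
    }
    if write_outputs:
        result.manifest = write_bins(bins, contigs, outdir, overwrite=overwrite)
        report_path = outdir / "run_report.json"
        report_path.write_text(json.dumps(result.report, indent=1, sort_keys=True))
        result.manifest["run_report.json"] = report_path
    return result


def _cached_default_model(cache_dir: Path | None, rng_seed: int) -> TDPModel:
    """Train (or reload) the bundled synthetic-genome model."""
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        path = cache_dir / "default_model.json"
        if path.exists():
            try:
                logger.info("reusing cached TDP model from %s", path)
                return TDPModel.load(path)
            except (ValueError, KeyError):
                pass
        model = default_model()
        model.save(path)
        return model
    return default_model()
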