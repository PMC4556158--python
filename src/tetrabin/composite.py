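"""Integration of the composition (TDP) and abundance (ADP) distances.

The composite pairwise distance is max(TDP, ADP) when TDP exceeds a small
switch threshold (0.05 by default) and the weighted mixture
ADP*w + TDP*(1-w) otherwise, with w growing with the number of informative
samples.  When ADP is undefined (no informative sample, or no coverage at
all) the composite reduces to TDP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .abundance import AbundanceConfig, CoverageProfile, adp_single_vec
from .tdp import TDPModel

__all__ = [
    "DEFAULT_TDP_SWITCH",
    "composite_distance",
    "DistanceMatrix",
    "CompositeDistanceProvider",
    "build_distance_matrix",
    "export_matrix_tsv",
]

DEFAULT_TDP_SWITCH = 0.05


def composite_distance(
    tdp: float,
    adp: float | None,
    w: float,
    tdp_switch: float = DEFAULT_TDP_SWITCH,
) -> float:
    """Single-pair composite distance; ``adp`` may be None/NaN (undefined)."""
    if not 0 <= w <= 1:
        raise ValueError(f"weight w must be in [0, 1], got {w}")
    if not 0 <= tdp <= 1:
        raise ValueError(f"tdp must be in [0, 1], got {tdp}")
    if adp is None or (isinstance(adp, float) and math.isnan(adp)):
        return tdp
    if tdp > tdp_switch:
        return max(tdp, adp)
    return adp * w + tdp * (1 - w)


@dataclass
class DistanceMatrix:
    """Dense symmetric composite-distance matrix over an ordered contig set."""

    contig_ids: list[str]
    lengths: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        n = len(self.contig_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match contig count")
        self._index = {cid: i for i, cid in enumerate(self.contig_ids)}

    def index_of(self, contig_id: str) -> int:
        return self._index[contig_id]

    def entry(self, id_i: str, id_j: str) -> float:
        return float(self.matrix[self._index[id_i], self._index[id_j]])

    def rows(self, i: int, js: np.ndarray) -> np.ndarray:
        return self.matrix[i, js]


class CompositeDistanceProvider:
    """Computes composite distances lazily, row by row.

    Produces results identical to the dense matrix from
    :func:`build_distance_matrix`; intended for contig sets too large for an
    n^2 matrix.  ``means``/``variances`` are (n_contigs, n_samples) arrays or
    None for TNF-only mode.
    """

    def __init__(
        self,
        contig_ids: list[str],
        lengths: np.ndarray,
        tnf_values: np.ndarray,
        model: TDPModel,
        means: np.ndarray | None = None,
        variances: np.ndarray | None = None,
        cfg: AbundanceConfig = AbundanceConfig(),
        tdp_switch: float = DEFAULT_TDP_SWITCH,
    ):
        n = len(contig_ids)
        if tnf_values.shape[0] != n or lengths.shape[0] != n:
            raise ValueError("contig ids, lengths and TNF matrix disagree in size")
        if (means is None) != (variances is None):
            raise ValueError("means and variances must be given together")
        if means is not None and (means.shape != variances.shape or means.shape[0] != n):
            raise ValueError("coverage arrays do not match the contig set")
        self.contig_ids = list(contig_ids)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.tnf_values = tnf_values
        self.model = model
        self.means = means
        self.variances = variances
        self.cfg = cfg
        self.tdp_switch = tdp_switch
        self._index = {cid: i for i, cid in enumerate(self.contig_ids)}
        self._log_m1 = math.log(cfg.weight_m + 1)

    def index_of(self, contig_id: str) -> int:
        return self._index[contig_id]

    @property
    def n_samples(self) -> int:
        return 0 if self.means is None else self.means.shape[1]

    def rows(self, i: int, js: np.ndarray) -> np.ndarray:
        """Composite distances from contig ``i`` to each contig in ``js``."""
        js = np.asarray(js, dtype=np.int64)
        d = np.linalg.norm(self.tnf_values[js] - self.tnf_values[i], axis=1)
        tdp = self.model.tdp(d, self.lengths[i], self.lengths[js])
        tdp = np.atleast_1d(np.asarray(tdp, dtype=float))
        if self.means is None or self.n_samples == 0:
            out = tdp.copy()
            out[js == i] = 0.0
            return out
        n_s = self.n_samples
        log_sum = np.zeros(js.size)
        n_inf = np.zeros(js.size, dtype=np.int64)
        for s in range(n_s):
            m1 = self.means[i, s]
            v1 = self.variances[i, s]
            m2 = self.means[js, s]
            v2 = self.variances[js, s]
            informative = (m1 > self.cfg.min_cv) | (m2 > self.cfg.min_cv)
            p = adp_single_vec(m1, v1, m2, v2, self.cfg.variance_floor)
            with np.errstate(divide="ignore"):
                lp = np.log(p)
            log_sum += np.where(informative, lp, 0.0)
            n_inf += informative
        with np.errstate(invalid="ignore"):
            adp = np.exp(log_sum / np.maximum(n_inf, 1))
        w = np.minimum(np.log(n_inf + 1) / self._log_m1, self.cfg.weight_alpha)
        mixed = adp * w + tdp * (1 - w)
        out = np.where(
            n_inf == 0, tdp, np.where(tdp > self.tdp_switch, np.maximum(tdp, adp), mixed)
        )
        out[js == i] = 0.0
        return out

    def pair(self, id_i: str, id_j: str) -> float:
        i, j = self._index[id_i], self._index[id_j]
        return float(self.rows(i, np.array([j]))[0])

    def dense(self) -> DistanceMatrix:
        n = len(self.contig_ids)
        mat = np.zeros((n, n))
        for i in range(n - 1):
            js = np.arange(i + 1, n)
            row = self.rows(i, js)
            mat[i, i + 1 :] = row
            mat[i + 1 :, i] = row
        return DistanceMatrix(self.contig_ids, self.lengths, mat)


def build_distance_matrix(
    contigs,
    tnf_values: np.ndarray,
    model: TDPModel,
    profiles: list[CoverageProfile] | None = None,
    cfg: AbundanceConfig = AbundanceConfig(),
    tdp_switch: float = DEFAULT_TDP_SWITCH,
) -> DistanceMatrix:
    """Dense composite-distance matrix for a (pre-filtered) contig set."""
    ids = [c.id for c in contigs]
    lengths = np.array([c.length for c in contigs], dtype=np.int64)
    means = variances = None
    if profiles is not None:
        by_id = {p.contig_id: p for p in profiles}
        missing = [cid for cid in ids if cid not in by_id]
        if missing:
            raise ValueError(f"coverage profiles missing for contigs: {missing[:5]}")
        means = np.stack([by_id[cid].means for cid in ids])
        variances = np.stack([by_id[cid].variances for cid in ids])
    provider = CompositeDistanceProvider(
        ids, lengths, tnf_values, model, means, variances, cfg, tdp_switch
    )
    return provider.dense()


def export_matrix_tsv(matrix: DistanceMatrix, path) -> None:
    """Write the strict upper triangle as (id_i, id_j, distance) rows."""
    with open(path, "w") as fh:
        fh.write("contig_i\tcontig_j\tdistance\n")
        n = len(matrix.contig_ids)
        for i in range(n - 1):
            for j in range(i + 1, n):
                fh.write(
                    f"{matrix.contig_ids[i]}\t{matrix.contig_ids[j]}\t"
                    f"{matrix.matrix[i, j]:.8f}\n"
                )
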