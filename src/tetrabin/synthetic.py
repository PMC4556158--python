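"""Synthetic benchmark communities with a ground-truth table.

Genomes are emitted by randomly drawn order-k Markov chains (giving each
genome a distinctive compositional signature), shredded into contigs with an
exponential length distribution above a minimum size, and given per-sample
depth tables whose variance exceeds the Poisson expectation by a fixed
overdispersion factor.  Everything is deterministic per (spec, seed) so
fixtures are generated at test time instead of being shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .abundance import CoverageProfile, write_depth_table
from .tnf import ContigRecord

__all__ = [
    "CommunitySpec",
    "TruthTable",
    "generate_genome",
    "shred_exponential",
    "simulate_depth_table",
    "make_fixture",
    "read_truth_table",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

try:  # optional JIT for the sequential Markov walk
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    _HAVE_NUMBA = False


def _walk_py(cum: np.ndarray, state: int, us: np.ndarray, out: np.ndarray, n_states: int):
    mod = n_states
    for t in range(us.shape[0]):
        row = cum[state]
        u = us[t]
        b = 0
        while row[b] < u:
            b += 1
        out[t] = b
        state = (state * 4 + b) % mod


if _HAVE_NUMBA:
    _walk = _njit(cache=False)(_walk_py)
else:  # pragma: no cover
    _walk = _walk_py


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic community."""

    n_genomes: int = 10
    genome_length: int = 3_000_000
    markov_order: int = 2
    n_samples: int = 5
    mean_depth_range: tuple[float, float] = (2.0, 50.0)
    overdispersion: float = 5.0
    contig_size_mean: int = 8000
    min_contig: int = 2500
    transition_sharpness: float = 5.0
    rng_seed: int = 42

    def __post_init__(self):
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1 (at least Poisson)")
        if self.min_contig >= self.contig_size_mean:
            raise ValueError("contig_size_mean must exceed min_contig")


@dataclass
class TruthTable:
    """Ground truth: (contig_id, genome_label, contig_length) per contig."""

    rows: list[tuple[str, str, int]]

    def genome_of(self) -> dict[str, str]:
        return {cid: label for cid, label, _ in self.rows}

    def length_of(self) -> dict[str, int]:
        return {cid: n for cid, _, n in self.rows}

    def genome_bases(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for _, label, n in self.rows:
            totals[label] = totals.get(label, 0) + n
        return totals


def generate_genome(
    markov_order: int,
    transition_sharpness: float,
    length: int,
    rng_seed: int,
) -> str:
    """One genome from a randomly drawn order-k Markov chain.

    Transition rows are Dirichlet(1/transition_sharpness) samples, so larger
    sharpness concentrates each row on fewer bases and makes the genome's
    4-mer signature more distinctive.
    """
    if markov_order < 0:
        raise ValueError("markov_order must be >= 0")
    if length < 10 * 4 ** (markov_order + 1):
        raise ValueError(
            f"length {length} too short for order {markov_order} "
            f"(need >= {10 * 4 ** (markov_order + 1)})"
        )
    if transition_sharpness <= 0:
        raise ValueError("transition_sharpness must be positive")
    rng = np.random.default_rng(rng_seed)
    n_states = 4**markov_order
    trans = rng.dirichlet(np.full(4, 1.0 / transition_sharpness), size=n_states)
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0 + 1e-12  # guard against u == 1 rounding

    head = rng.integers(0, 4, size=max(markov_order, 1))
    state = 0
    for b in head[:markov_order]:
        state = state * 4 + int(b)
    n_walk = length - markov_order
    us = rng.random(n_walk)
    out = np.empty(n_walk, dtype=np.int64)
    _walk(cum, state, us, out, n_states)
    codes = np.concatenate([head[:markov_order], out])
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def shred_exponential(
    genome: str,
    contig_size_mean: int,
    min_contig: int,
    rng_seed: int,
    label: str = "g",
) -> list[ContigRecord]:
    """Tile a genome into contigs of length min_contig + Exponential.

    The exponential scale is contig_size_mean - min_contig so the emitted
    lengths average contig_size_mean; a trailing remainder below min_contig
    is discarded.
    """
    if len(genome) <= min_contig:
        raise ValueError("genome must be longer than min_contig")
    rng = np.random.default_rng(rng_seed)
    scale = contig_size_mean - min_contig
    contigs: list[ContigRecord] = []
    pos = 0
    n = len(genome)
    k = 0
    while n - pos >= min_contig:
        length = min_contig + int(rng.exponential(scale))
        length = min(length, n - pos)
        contigs.append(ContigRecord(f"{label}_{k:05d}", genome[pos : pos + length]))
        pos += length
        k += 1
    return contigs


def simulate_depth_table(
    truth: TruthTable, spec: CommunitySpec
) -> list[CoverageProfile]:
    """Per-sample coverage with super-Poisson variance.

    Each genome draws a true abundance per sample log-uniformly on
    mean_depth_range; each contig reports a mean depth drawn around it with
    noise variance a*k*1000/contig_length (longer contigs estimate their
    depth more tightly), truncated at zero, and a reported variance of
    k * mean with k the overdispersion factor.
    """
    if not truth.rows:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 3]))
    labels = sorted({label for _, label, _ in truth.rows})
    lo, hi = spec.mean_depth_range
    abundance = {
        g: np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_samples))
        for g in labels
    }
    k = spec.overdispersion
    profiles: list[CoverageProfile] = []
    for cid, label, length in truth.rows:
        a = abundance[label]
        noise_sd = np.sqrt(a * k * 1000.0 / length)
        mean = np.clip(rng.normal(a, noise_sd), 0.0, None)
        profiles.append(CoverageProfile(cid, mean, k * mean))
    return profiles


def build_community(
    spec: CommunitySpec,
) -> tuple[list[ContigRecord], list[CoverageProfile], TruthTable]:
    """Generate contigs, coverage profiles and truth for one community."""
    ss = np.random.SeedSequence([spec.rng_seed, 1])
    genome_seeds = ss.spawn(spec.n_genomes)
    shred_ss = np.random.SeedSequence([spec.rng_seed, 2]).spawn(spec.n_genomes)
    contigs: list[ContigRecord] = []
    rows: list[tuple[str, str, int]] = []
    for gi in range(spec.n_genomes):
        label = f"genome{gi:02d}"
        genome = generate_genome(
            spec.markov_order,
            spec.transition_sharpness,
            spec.genome_length,
            int(genome_seeds[gi].generate_state(1)[0]),
        )
        parts = shred_exponential(
            genome,
            spec.contig_size_mean,
            spec.min_contig,
            int(shred_ss[gi].generate_state(1)[0]),
            label=label,
        )
        contigs.extend(parts)
        rows.extend((c.id, label, c.length) for c in parts)
    truth = TruthTable(rows)
    profiles = simulate_depth_table(truth, spec)
    return contigs, profiles, truth


def make_fixture(
    spec: CommunitySpec, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Write assembly FASTA, depth TSV and truth TSV; byte-stable per spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, profiles, truth = build_community(spec)
    fasta = outdir / "assembly.fasta"
    with open(fasta, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for k in range(0, c.length, 80):
                fh.write(c.sequence[k : k + 80] + "\n")
    depth = outdir / "depth.tsv"
    write_depth_table(depth, profiles, truth.length_of())
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("contig_id\tgenome_label\tcontig_length\n")
        for cid, label, n in truth.rows:
            fh.write(f"{cid}\t{label}\t{n}\n")
    return fasta, depth, truth_path


def read_truth_table(path: str | Path) -> TruthTable:
    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["contig_id", "genome_label", "contig_length"]:
            raise ValueError(f"{path}: unexpected truth-table header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, label, n = line.split("\t")
            rows.append((cid, label, int(n)))
    return TruthTable(rows)
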