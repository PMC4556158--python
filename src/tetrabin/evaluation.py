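"""Base-weighted precision/recall scoring of bins against a truth table.

Precision is the fraction of a bin's bases that originate from its dominant
genome; recall is the fraction of that genome's assembled bases the bin
captures.  A genome counts as recovered ("good") when some bin assigns it
precision and recall strictly above the thresholds (defaults 0.9 and 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .binning import Bin
from .synthetic import TruthTable

__all__ = ["BinScore", "score_bins", "count_good_genomes", "write_scores"]


@dataclass(frozen=True)
class BinScore:
    bin_id: int
    best_genome: str
    precision: float
    recall: float
    bin_bases: int
    genome_bases: int


def score_bins(bins: list[Bin], truth: TruthTable) -> list[BinScore]:
    """Score each bin against its dominant genome (ties -> larger genome)."""
    genome_of = truth.genome_of()
    length_of = truth.length_of()
    genome_bases = truth.genome_bases()
    scores: list[BinScore] = []
    for b in bins:
        shared: dict[str, int] = {}
        bin_bases = 0
        for cid in b.member_ids:
            if cid not in genome_of:
                raise ValueError(f"bin {b.bin_id}: contig {cid!r} absent from truth table")
            g = genome_of[cid]
            n = length_of[cid]
            shared[g] = shared.get(g, 0) + n
            bin_bases += n
        best = max(shared, key=lambda g: (shared[g], genome_bases[g]))
        scores.append(
            BinScore(
                bin_id=b.bin_id,
                best_genome=best,
                precision=shared[best] / bin_bases,
                recall=shared[best] / genome_bases[best],
                bin_bases=bin_bases,
                genome_bases=genome_bases[best],
            )
        )
    return scores


def count_good_genomes(
    scores: list[BinScore],
    precision_min: float = 0.9,
    recall_min: float = 0.3,
) -> int:
    """Distinct genomes with at least one bin strictly above both thresholds."""
    good = {
        s.best_genome
        for s in scores
        if s.precision > precision_min and s.recall > recall_min
    }
    return len(good)


def write_scores(scores: list[BinScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\tbest_genome\tprecision\trecall\tbin_bases\tgenome_bases\n")
        for s in scores:
            fh.write(
                f"{s.bin_id}\t{s.best_genome}\t{s.precision:.6f}\t{s.recall:.6f}\t"
                f"{s.bin_bases}\t{s.genome_bases}\n"
            )
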