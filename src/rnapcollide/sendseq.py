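"""SEnd-seq computational pipeline: orientation calls, end filters, and
transcript-length profiles.

SEnd-seq reads out both ends of each RNA: a 5'-end read and a 3'-end read
per molecule.  On a convergent two-promoter template each molecule comes
from either the forward or the reverse transcription unit, so both reads
are locally aligned against both candidate RNAs and the orientation with
the higher summed score wins.  Calls are then filtered: the mapped ends
must be more than ``min_end_separation`` nucleotides apart, and the 5'
end must fall within the start-site window.  Transcript coordinates are
1-based and fully closed.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .biochem import compare_conditions

__all__ = [
    "AlignmentParams",
    "TemplateSpec",
    "ClassifiedRead",
    "local_align",
    "classify_pair",
    "length_profiles",
    "compare_length_distributions",
]

_VALID = set("ACGTU")


@dataclasses.dataclass(frozen=True)
class AlignmentParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch score must be <= 0")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("need gap_open <= gap_extend <= 0")


@dataclasses.dataclass(frozen=True)
class TemplateSpec:
    """Candidate RNA sequences for the forward and reverse units.

    Both RNAs are stored 5'->3' so their transcription start sites sit at
    position 1 of their own coordinate systems.
    """

    forward_rna: str
    reverse_rna: str
    forward_tss: int = 1
    reverse_tss: int = 1
    hairpin_region: tuple[int, int] | None = None  # template coords, closed
    tss_window: int = 10  # nt; interpreted as |5' end - TSS| <= window / 2
    min_end_separation: int = 15  # nt, strict inequality

    def __post_init__(self) -> None:
        for name in ("forward_rna", "reverse_rna"):
            seq = getattr(self, name).upper()
            if not seq or set(seq) - _VALID:
                raise ValueError(f"{name} must be a non-empty sequence over ACGU/T")
            object.__setattr__(self, name, seq)
        if self.hairpin_region is not None:
            s, e = self.hairpin_region
            n = max(len(self.forward_rna), len(self.reverse_rna))
            if not (1 <= s <= e <= n):
                raise ValueError("hairpin_region outside sequence bounds")


@dataclasses.dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    orientation: str  # "forward" | "reverse" | "unmapped"
    five_prime: int  # 1-based template coordinate of the mapped 5' end
    three_prime: int  # 1-based template coordinate of the mapped 3' end
    score_forward: float
    score_reverse: float
    filters_failed: frozenset  # subset of {short_separation, tss_window, ambiguous}

    @property
    def length(self) -> int:
        return self.three_prime - self.five_prime + 1

    @property
    def mapped(self) -> bool:
        return self.orientation != "unmapped"


def _normalise(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def local_align(
    query: str,
    reference: str,
    params: AlignmentParams | None = None,
    max_tied: int = 64,
) -> tuple[float, int, int]:
    """Best local (Smith-Waterman, affine gaps) alignment of query in reference.

    Returns ``(score, ref_start, ref_end)`` with 1-based closed reference
    coordinates.  Among co-optimal alignments the one with the smallest
    reference start, then the shortest span, is reported (at most
    ``max_tied`` co-optimal alignments are inspected).
    """
    params = params or AlignmentParams()
    q = _normalise(query)
    r = _normalise(reference)
    if not q or not r:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(params)
    alignments = aligner.align(r, q)
    try:
        first = alignments[0]
    except IndexError:
        return 0.0, 0, 0
    score = float(first.score)
    best: tuple[int, int] | None = None
    for i, aln in enumerate(alignments):
        if i >= max_tied or float(aln.score) < score:
            break
        start = int(aln.aligned[0][0][0]) + 1
        end = int(aln.aligned[0][-1][1])
        cand = (start, end - start)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return score, best[0], best[0] + best[1]


def classify_pair(
    five_read: str,
    three_read: str,
    template: TemplateSpec,
    params: AlignmentParams | None = None,
    read_id: str = "",
) -> ClassifiedRead:
    """Assign a read pair to the forward or reverse transcription unit.

    Per orientation the score is the sum of the best local alignment of the
    5'-end read and of the 3'-end read against that orientation's RNA; the
    higher total wins, with exact ties reported as ambiguous.  The mapped
    5' end is the alignment start of the 5' read; the 3' end is the
    alignment end of the 3' read.  Separation and TSS-window filters are
    applied afterwards and failures recorded — a read that fails any filter
    is reported as unmapped, per the classification contract.
    """
    params = params or AlignmentParams()
    per_orient = {}
    for orient, rna, tss in (
        ("forward", template.forward_rna, template.forward_tss),
        ("reverse", template.reverse_rna, template.reverse_tss),
    ):
        s5, start5, _ = local_align(five_read, rna, params)
        s3, _, end3 = local_align(three_read, rna, params)
        per_orient[orient] = {
            "score": s5 + s3,
            "five": start5,
            "three": end3,
            "tss": tss,
        }

    sf = per_orient["forward"]["score"]
    sr = per_orient["reverse"]["score"]
    failed: set[str] = set()
    if sf == sr:
        failed.add("ambiguous")
        winner = per_orient["forward"]
    else:
        winner = per_orient["forward"] if sf > sr else per_orient["reverse"]
    orientation = "forward" if winner is per_orient["forward"] else "reverse"

    five, three = winner["five"], winner["three"]
    if not (three - five > template.min_end_separation):
        failed.add("short_separation")
    if abs(five - winner["tss"]) > template.tss_window / 2:
        failed.add("tss_window")

    return ClassifiedRead(
        read_id=read_id,
        orientation="unmapped" if failed else orientation,
        five_prime=five,
        three_prime=three,
        score_forward=sf,
        score_reverse=sr,
        filters_failed=frozenset(failed),
    )


def length_profiles(
    reads: Iterable[ClassifiedRead],
    template: TemplateSpec,
    boundary_window: int = 5,
) -> dict:
    """Transcript-length lists, 3'-end histogram, and hairpin drop statistic.

    The drop statistic is the mean 3'-end-survival coverage over the
    ``boundary_window`` nucleotides just upstream of the hairpin start,
    divided by the mean over the window just downstream: large values mean
    transcripts pile up at the hairpin boundary instead of reading through.
    """
    mapped = [r for r in reads if r.mapped]
    if not mapped:
        raise ValueError("no mapped reads")

    lengths: dict[str, list[int]] = {"forward": [], "reverse": []}
    for r in mapped:
        lengths[r.orientation].append(r.length)

    n = max(len(template.forward_rna), len(template.reverse_rna))
    hist = np.zeros(n + 1, dtype=int)  # index = 3' end template coordinate
    for r in mapped:
        if 1 <= r.three_prime <= n:
            hist[r.three_prime] += 1

    drop = None
    if template.hairpin_region is not None:
        b = template.hairpin_region[0]
        # coverage(pos): reads whose transcript still extends to pos
        ends = np.array([r.three_prime for r in mapped])
        cov = lambda pos: float(np.sum(ends >= pos))
        before = [cov(p) for p in range(b - boundary_window, b)]
        after = [cov(p) for p in range(b + 1, b + 1 + boundary_window)]
        num, den = float(np.mean(before)), float(np.mean(after))
        drop = np.inf if den == 0 else num / den

    return {
        "lengths": lengths,
        "three_prime_histogram": hist,
        "hairpin_drop": drop,
        "n_mapped": len(mapped),
    }


def compare_length_distributions(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Welch t-test between two transcript-length samples: (t, p)."""
    res = compare_conditions({"a": list(a), "b": list(b)}, correct=False)[0]
    return res["t"], res["p"]
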