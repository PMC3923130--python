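"""Deterministic global pairwise alignment of microRNA sequences.

Hairpins are short (~60-150 nt), so optimal global (Needleman-Wunsch style)
alignment with an affine gap penalty is used both for ortholog pairing scores
and for the alignments that feed divergence estimation. The default scheme
rewards a match +2 and penalises a mismatch -3 (the classic megablast-like
r/q used for short, highly similar nucleotide sequences); gaps are penalised
-5 to open and -2 to extend, discouraging spurious gapped hits on short
hairpins.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

_VALID = set("ACGTN")


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme (a gap of length L costs open + (L-1)*extend)."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T) alphabet; validate characters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def score_similarity(query: str, target: str, scoring: Scoring | None = None) -> float:
    """Optimal global alignment score between two nucleotide sequences.

    Deterministic; raises ``ValueError`` on empty input.
    """
    if not query or not target:
        raise ValueError("cannot score an empty sequence")
    scoring = scoring or Scoring()
    return float(_aligner(scoring).score(normalize_seq(query), normalize_seq(target)))


def align_global(seq_a: str, seq_b: str, scoring: Scoring | None = None) -> tuple[str, str, float]:
    """Optimal global alignment; returns (gapped A, gapped B, score).

    Ties between co-optimal alignments are broken by the aligner's canonical
    enumeration order, so output is deterministic for given inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or Scoring()
    a = normalize_seq(seq_a)
    b = normalize_seq(seq_b)
    aln = _aligner(scoring).align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)
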