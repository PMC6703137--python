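"""Allele-specific transcription-factor motif disruption scoring.

A PWM is scanned in log-odds space over every window of a probe sequence on
both strands; the per-window score in bits is

    score = sum_j log2( (f[b_j, j] + c * bg[b_j]) / (bg[b_j] * (1 + c)) )

with f the motif probabilities, bg the background, and c a small
pseudocount. For a SNP embedded in a pair of allele probes, the impact of
the allele swap on a motif is the difference of the best window scores,
restricted to windows that overlap the variant base — windows elsewhere are
identical between alleles, so the delta is local by construction. Motifs
are ranked by |delta|; no binding-call threshold is imposed.
"""

from __future__ import annotations

from .errors import DomainError, SequenceError
from .types import ALPHABET, VALID_BASES, AlleleImpact, AlleleProbePair, PWM, revcomp

import numpy as np


def pwm_logodds_scan(
    seq: str, pwm: PWM, pseudocount: float = 1e-4
) -> list[tuple[int, str, float]]:
    """Score every length-L window of ``seq`` on both strands.

    Returns (start, strand, score_bits) triples; ``start`` is the window's
    0-based start on the given sequence for both strands (a '-' entry is the
    score of the window's reverse complement).
    """
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise SequenceError(f"sequence contains non-ACGT characters: {bad}")
    L = pwm.length
    if len(seq) < L:
        raise DomainError(
            f"sequence length {len(seq)} shorter than motif {pwm.motif_id} (L={L})"
        )
    if pseudocount < 0:
        raise DomainError("pseudocount must be >= 0")
    bg = pwm.background
    # log-odds lookup per (column, base), pseudocount mixed with background
    logodds = np.log2(
        (pwm.probs + pseudocount * bg[None, :]) / (bg[None, :] * (1.0 + pseudocount))
    )
    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    fwd = np.array([base_idx[b] for b in seq])
    rev = np.array([base_idx[b] for b in revcomp(seq)])
    n = len(seq)
    out: list[tuple[int, str, float]] = []
    cols = np.arange(L)
    for start in range(n - L + 1):
        plus = float(logodds[cols, fwd[start : start + L]].sum())
        # '-' window at seq[start:start+L] is positions n-start-L .. on the rc
        rc_start = n - start - L
        minus = float(logodds[cols, rev[rc_start : rc_start + L]].sum())
        out.append((start, "+", plus))
        out.append((start, "-", minus))
    return out


def _best_over_snp(
    seq: str, pwm: PWM, snp_offset: int, pseudocount: float
) -> tuple[float, tuple[int, str]]:
    L = pwm.length
    best, best_win = -np.inf, (0, "+")
    for start, strand, score in pwm_logodds_scan(seq, pwm, pseudocount):
        if start <= snp_offset < start + L and score > best:
            best, best_win = score, (start, strand)
    return best, best_win


def allele_delta(
    pair: AlleleProbePair, pwms: list[PWM], pseudocount: float = 1e-4
) -> list[AlleleImpact]:
    """Per-motif change of the best variant-overlapping match between alleles.

    delta = best_alt_score - best_ref_score in bits; negative values mean
    the alternative allele weakens the best motif match. Results are sorted
    by |delta| descending (ties by motif id).
    """
    impacts = []
    for pwm in pwms:
        if pwm.length > len(pair.ref_seq):
            raise DomainError(
                f"motif {pwm.motif_id} (L={pwm.length}) longer than probe "
                f"({len(pair.ref_seq)} bp)"
            )
        ref_best, _ = _best_over_snp(pair.ref_seq, pwm, pair.snp_offset, pseudocount)
        alt_best, alt_win = _best_over_snp(
            pair.alt_seq, pwm, pair.snp_offset, pseudocount
        )
        impacts.append(
            AlleleImpact(
                motif_id=pwm.motif_id,
                best_ref_score=ref_best,
                best_alt_score=alt_best,
                best_window=alt_win,
            )
        )
    impacts.sort(key=lambda im: (-abs(im.delta), im.motif_id))
    return impacts
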