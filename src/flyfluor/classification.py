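"""Genotype assignment in heterogeneous groups from combined scores.

Two rules are available, mirroring whether the experimenter knows how many
labeled animals were placed in the arena:

* threshold mode — apply the calibrated operating point; ``score >=
  threshold`` is called GFP (boundary inclusive on the GFP side);
* prior-count mode — sort scores descending and call the top N flies GFP,
  N being the expected number of GFP animals. This uses strictly more
  information and never produces the wrong class count.

Ties in prior-count mode are broken by ascending fly_id so results are
deterministic and permutation-invariant.
"""

from __future__ import annotations

from typing import Sequence

from .io_data import IdentityCall, Label


def classify_by_threshold(
    scores: Sequence[tuple[int, float]], threshold: float
) -> list[IdentityCall]:
    """Call each fly GFP when its score is >= ``threshold``.

    The margin is the distance of the score from the boundary.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    return [
        IdentityCall(
            fly_id=fly_id,
            label=Label.GFP if score >= threshold else Label.NON_GFP,
            score=float(score),
            margin=abs(float(score) - threshold),
        )
        for fly_id, score in scores
    ]


def classify_by_prior_count(
    scores: Sequence[tuple[int, float]], n_gfp: int
) -> list[IdentityCall]:
    """Call the ``n_gfp`` highest-scoring flies GFP, the rest non-GFP.

    The margin is the distance from the cut value: the midpoint between the
    scores at descending ranks N and N+1 (the boundary score itself when
    ``n_gfp`` is 0 or the whole group). Calls are returned in ascending
    fly_id order.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    if not (0 <= n_gfp <= len(scores)):
        raise ValueError(
            f"n_gfp={n_gfp} out of range for a group of {len(scores)} flies"
        )
    ranked = sorted(scores, key=lambda fs: (-fs[1], fs[0]))
    if n_gfp == 0:
        cut = ranked[0][1]
    elif n_gfp == len(ranked):
        cut = ranked[-1][1]
    else:
        cut = (ranked[n_gfp - 1][1] + ranked[n_gfp][1]) / 2.0
    gfp_ids = {fly_id for fly_id, _ in ranked[:n_gfp]}
    calls = [
        IdentityCall(
            fly_id=fly_id,
            label=Label.GFP if fly_id in gfp_ids else Label.NON_GFP,
            score=float(score),
            margin=abs(float(score) - cut),
        )
        for fly_id, score in ranked
    ]
    return sorted(calls, key=lambda c: c.fly_id)
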