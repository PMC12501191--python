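"""Background dependence of substitutions and mutation-effect trajectories.

A mutation's effect in a given background is the shift it induces in the
product composition (the difference vector mutant - background, which sums
to zero), together with the normalised functional distance of the mutant
from its background and the gain in a focal product's fraction.  Comparing
the same mutation's effect vectors across two backgrounds with the
half-L1 divergence ``0.5 * sum|delta1_i - delta2_i|`` (bounded in [0, 2],
zero iff the effects are identical) turns qualitative "the effect depends
on the background" observations into a statistic.

Loss-of-function mutants (no detectable products) are a distinct category:
they carry no effect vector, are excluded from divergence scores with an
explicit incomparable marker (never a silent zero), and are counted in a
rescue analysis when a second mutation restores activity.

The trajectory view tracks a mutation's focal-product gain across an
ordered path of ancestors, with the x-axis scaled to cumulative masked
Hamming distances between consecutive ancestors, plus per-interval fold
changes of the mean focal fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncomparableEffectsError, InputError
from .funcspace import FOCAL_PRODUCT, functional_distance
from .profiling import ProductProfile
from .variants import hamming_distance


@dataclass
class MutationEffect:
    """Effect of one mutation in one genetic background."""

    background: str
    code: str
    products: tuple
    delta: np.ndarray | None          # mutant - background; None if LOF
    functional_distance: float | None
    focal_gain: float | None
    loss_of_function: bool = False

    def __post_init__(self):
        if self.loss_of_function:
            if self.delta is not None:
                raise InputError("loss-of-function effects carry no delta vector")
        else:
            self.delta = np.asarray(self.delta, float)
            if abs(self.delta.sum()) > 1e-9:
                raise InputError("effect delta must sum to 0")
            if self.functional_distance is not None and self.functional_distance < 0:
                raise InputError("functional distance must be >= 0")

    def delta_dict(self) -> dict:
        if self.loss_of_function:
            return {}
        return dict(zip(self.products, self.delta))


def mutation_effect(background: ProductProfile, mutant: ProductProfile,
                    reference=None, focal: str = FOCAL_PRODUCT,
                    code: str = "") -> MutationEffect:
    """Measure a mutation's compositional effect in its background.

    The background must be active; an inactive mutant yields a
    loss-of-function effect (no delta vector).
    """
    if not background.active:
        raise InputError(f"background {background.enzyme!r} is inactive; "
                         "effects are undefined")
    code = code or mutant.enzyme
    if not mutant.active:
        return MutationEffect(background.enzyme, code, (), None, None, None,
                              loss_of_function=True)
    bd, md = background.as_dict(), mutant.as_dict()
    vocab = tuple(dict.fromkeys(list(bd) + list(md)))
    bv = np.array([bd.get(p, 0.0) for p in vocab])
    mv = np.array([md.get(p, 0.0) for p in vocab])
    fd = functional_distance(md, bd, reference)
    focal_gain = (md.get(focal, 0.0)) - (bd.get(focal, 0.0))
    return MutationEffect(background.enzyme, code, vocab, mv - bv, fd,
                          float(focal_gain))


def effect_divergence(e1: MutationEffect, e2: MutationEffect,
                      require_same_code: bool = True) -> float:
    """Half-L1 distance between two effect vectors, in [0, 2].

    Quantifies background dependence of one mutation measured in two
    backgrounds.  Raises :class:`IncomparableEffectsError` when either
    effect is a loss of function.
    """
    if require_same_code and e1.code != e2.code:
        raise InputError(f"effects compare different mutations "
                         f"({e1.code!r} vs {e2.code!r})")
    if e1.loss_of_function or e2.loss_of_function:
        raise IncomparableEffectsError(
            f"effect of {e1.code!r} is a loss of function in "
            f"{e1.background if e1.loss_of_function else e2.background!r}; "
            "divergence is reported separately, never as 0")
    d1, d2 = e1.delta_dict(), e2.delta_dict()
    vocab = dict.fromkeys(list(d1) + list(d2))
    return 0.5 * sum(abs(d1.get(p, 0.0) - d2.get(p, 0.0)) for p in vocab)


def divergence_table(effects) -> pd.DataFrame:
    """All pairwise same-mutation divergences across backgrounds.

    One row per (mutation, background pair); loss-of-function pairs are kept
    with status ``incomparable`` and a NaN score.
    """
    by_code = {}
    for e in effects:
        by_code.setdefault(e.code, []).append(e)
    rows = []
    for code, group in by_code.items():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                e1, e2 = group[i], group[j]
                try:
                    score = effect_divergence(e1, e2)
                    status = "ok"
                except IncomparableEffectsError:
                    score, status = np.nan, "incomparable (loss of function)"
                rows.append({"mutation": code, "background_1": e1.background,
                             "background_2": e2.background,
                             "divergence": score, "status": status})
    return pd.DataFrame(rows)


def rescued(single: MutationEffect, combo: MutationEffect) -> bool:
    """True when a loss-of-function single mutation regains activity in combo."""
    if not single.loss_of_function:
        raise InputError(f"{single.code!r} is not a loss-of-function effect")
    return not combo.loss_of_function


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryPoint:
    """One ancestor on the Hamming-scaled mutation-effect trajectory."""

    ancestor: str
    x: int            # cumulative masked Hamming distance from the first ancestor
    interval: int     # masked Hamming distance to the previous ancestor
    mean: float       # mean focal-product fraction of the mutant (NaN if missing)
    sd: float
    n: int

    @property
    def missing(self) -> bool:
        return not math.isfinite(self.mean)


def iso_trajectory(ancestors, mutant_profiles, focal: str = FOCAL_PRODUCT,
                   site_mask=None, numbering=None) -> list:
    """Focal-product formation by a tracked mutation along an ancestor path.

    Parameters
    ----------
    ancestors : ordered sequence of (id, sequence) pairs along the path.
    mutant_profiles : mapping ancestor id -> ProductProfile of the tracked
        mutant in that background (None/absent = missing point).
    site_mask : optional reference positions (e.g. the alpha domain) for the
        Hamming x-axis.
    """
    ancestors = list(ancestors)
    if len(ancestors) < 1:
        raise InputError("trajectory needs at least one ancestor")
    points = []
    x = 0
    prev_seq = None
    for anc_id, seq in ancestors:
        interval = 0
        if prev_seq is not None:
            interval = hamming_distance(prev_seq, seq, site_mask=site_mask,
                                        numbering=numbering)
            x += interval
        prof = mutant_profiles.get(anc_id)
        if prof is None or not prof.active:
            mean, sd, n = np.nan, np.nan, 0
        else:
            mean = prof.fraction(focal)
            sd = prof.sd_of(focal)
            n = prof.n
        points.append(TrajectoryPoint(anc_id, x, interval, float(mean),
                                      float(sd), n))
        prev_seq = seq
    return points


@dataclass
class FoldChange:
    """Per-interval fold change of the mean focal fraction."""

    from_ancestor: str
    to_ancestor: str
    fold: float | None         # None when undefined (from zero)
    from_zero: bool = False

    @property
    def defined(self) -> bool:
        return self.fold is not None


def fold_changes(trajectory) -> list:
    """Ratios of consecutive nonmissing trajectory means.

    Intervals starting from a mean of exactly zero are reported as
    undefined-from-zero rather than infinite.
    """
    pts = [p for p in trajectory if not p.missing]
    if len(pts) < 2:
        raise InputError("fold changes need >= 2 trajectory points with "
                         "nonmissing means")
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        if a.mean == 0:
            out.append(FoldChange(a.ancestor, b.ancestor, None, from_zero=True))
        else:
            out.append(FoldChange(a.ancestor, b.ancestor, b.mean / a.mean))
    return out


def trajectory_frame(trajectory) -> pd.DataFrame:
    return pd.DataFrame([{"ancestor": p.ancestor, "x": p.x,
                          "interval": p.interval, "mean": p.mean,
                          "sd": p.sd, "n": p.n} for p in trajectory])
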