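"""History-conditioned receptive fields and attention-axis shifts.

A cell's receptive field is its mean evoked response to each of the 9
whiskers on a grid centered on its columnar whisker (CW), with offsets
(dx, dy) in {-1, 0, 1}^2 (x rostral-positive along arcs, y up-positive
along rows). Comparing the field measured after prior-NoGo trials with
the field measured after a multi-hit streak to an attentional target
whisker quantifies attention-driven tuning shifts: the center of mass
(CoM) of each field is projected onto the axis from the CW to the
target, and the shift is normalized by the CW-to-target distance, so
+1 means the CoM moved the full way to the target and negative values
are shifts away from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReceptiveField",
    "RFShiftResult",
    "RFModulation",
    "best_whisker",
    "rf_com",
    "rf_shift_along_attention_axis",
    "rf_modulation",
    "receptive_field_for_condition",
    "rf_shift_per_cell",
]

#: Row-major order of the 9 offsets, used for deterministic tie-breaks.
OFFSETS = tuple((dx, dy) for dy in (1, 0, -1) for dx in (-1, 0, 1))

MIN_SAMPLED_POSITIONS = 6


@dataclass(frozen=True)
class ReceptiveField:
    """A 9-whisker response map on the CW-centered offset grid.

    values/sampled map offset (dx, dy) -> mean evoked response / whether
    that whisker was sampled for this cell and condition. Values may be
    negative (evoked differences).
    """

    values: dict
    sampled: dict
    condition: str = ""
    cell_id: str = ""

    def sampled_offsets(self) -> list[tuple[int, int]]:
        return [o for o in OFFSETS if self.sampled.get(o, False)]

    def restrict(self, mask) -> "ReceptiveField":
        """The same field with sampling restricted to ``mask`` offsets."""
        keep = set(mask)
        return ReceptiveField(
            values={o: v for o, v in self.values.items() if o in keep},
            sampled={o: (self.sampled.get(o, False) and o in keep)
                     for o in OFFSETS},
            condition=self.condition, cell_id=self.cell_id)


@dataclass(frozen=True)
class RFShiftResult:
    """Center-of-mass shift of one cell along the attention axis."""

    com_nogo: tuple[float, float]
    com_attend: tuple[float, float]
    target_offset: tuple[int, int]
    shift: float
    n_targets_averaged: int = 1


@dataclass(frozen=True)
class RFModulation:
    """CW/SW response modulation when attention is on the CW.

    rmi_cw / rmi_sw are (attend - nogo)/|attend + nogo| for CW and
    top-3 SW responses; cw_preference_* are (CW - SW)/|CW + SW| within
    each condition.
    """

    rmi_cw: float | None
    rmi_sw: float | None
    cw_preference_attend: float | None
    cw_preference_nogo: float | None


def _norm_index(a: float, b: float, eps: float = 1e-9) -> float | None:
    denom = abs(a + b)
    if denom < eps:
        return None
    return float((a - b) / denom)


def best_whisker(rf: ReceptiveField) -> tuple[tuple[int, int], bool]:
    """Offset of the highest-magnitude sampled response.

    Ties are broken by row-major offset order; returns (offset,
    tie_flag).
    """
    offsets = rf.sampled_offsets()
    if not offsets:
        raise ValueError("receptive field has no sampled positions")
    best = max(offsets, key=lambda o: (rf.values[o], -OFFSETS.index(o)))
    ties = [o for o in offsets
            if o != best and np.isclose(rf.values[o], rf.values[best])]
    # row-major tie-break: earliest offset in OFFSETS wins
    candidates = [best] + ties
    winner = min(candidates, key=OFFSETS.index)
    return winner, bool(ties)


def rf_com(rf: ReceptiveField, clip_negative: bool = True
           ) -> tuple[float, float]:
    """Response-weighted mean offset of the sampled positions.

    Negative evoked values are clipped at 0 for weighting (a signed
    field has no well-defined CoM). Raises when the total clipped
    weight is not positive.
    """
    offsets = rf.sampled_offsets()
    if not offsets:
        raise ValueError("receptive field has no sampled positions")
    w = np.array([rf.values[o] for o in offsets], dtype=float)
    if clip_negative:
        w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("nonpositive total weight; CoM undefined")
    xy = np.array(offsets, dtype=float)
    com = (w[:, None] * xy).sum(axis=0) / total
    return (float(com[0]), float(com[1]))


def rf_shift_along_attention_axis(rf_nogo: ReceptiveField,
                                  rf_attend: ReceptiveField,
                                  target_offset: tuple[int, int],
                                  ) -> RFShiftResult:
    """Normalized CoM shift toward an attentional target whisker.

    Both fields are restricted to the intersection of their sampling
    masks (values at non-shared positions cannot influence the result);
    at least 6 of the 9 positions must be sampled in both conditions.
    shift = (CoM_attend - CoM_nogo) . u / ||target|| with u the unit
    vector from the CW to the target.
    """
    shared = [o for o in OFFSETS
              if rf_nogo.sampled.get(o, False)
              and rf_attend.sampled.get(o, False)]
    if len(shared) < MIN_SAMPLED_POSITIONS:
        raise ValueError(
            f"only {len(shared)} positions sampled in both conditions; "
            f"need >= {MIN_SAMPLED_POSITIONS}")
    target = np.asarray(target_offset, dtype=float)
    norm = np.linalg.norm(target)
    if norm == 0:
        raise ValueError("target offset must be a surround whisker")
    com_nogo = np.array(rf_com(rf_nogo.restrict(shared)))
    com_attend = np.array(rf_com(rf_attend.restrict(shared)))
    u = target / norm
    shift = float((com_attend - com_nogo) @ u / norm)
    return RFShiftResult(com_nogo=tuple(com_nogo), com_attend=tuple(com_attend),
                         target_offset=tuple(int(v) for v in target_offset),
                         shift=shift)


def rf_modulation(rf_attend: ReceptiveField, rf_nogo: ReceptiveField
                  ) -> RFModulation:
    """CW and surround-whisker modulation when attending the CW.

    The SW term averages the 3 surround whiskers with the strongest
    prior-NoGo responses (ties broken row-major). CW is the (0, 0)
    offset.
    """
    cw = (0, 0)
    if not (rf_nogo.sampled.get(cw) and rf_attend.sampled.get(cw)):
        raise ValueError("CW must be sampled in both conditions")
    shared_sw = [o for o in OFFSETS if o != cw
                 and rf_nogo.sampled.get(o, False)
                 and rf_attend.sampled.get(o, False)]
    if len(shared_sw) < 3:
        raise ValueError("need >= 3 shared surround whiskers")
    top3 = sorted(shared_sw,
                  key=lambda o: (-rf_nogo.values[o], OFFSETS.index(o)))[:3]
    cw_a, cw_n = rf_attend.values[cw], rf_nogo.values[cw]
    sw_a = float(np.mean([rf_attend.values[o] for o in top3]))
    sw_n = float(np.mean([rf_nogo.values[o] for o in top3]))
    return RFModulation(
        rmi_cw=_norm_index(cw_a, cw_n),
        rmi_sw=_norm_index(sw_a, sw_n),
        cw_preference_attend=_norm_index(cw_a, sw_a),
        cw_preference_nogo=_norm_index(cw_n, sw_n),
    )


# ---------------------------------------------------------------------------
# builders from session data


def receptive_field_for_condition(evoked_col: np.ndarray, session, labels,
                                  cw: str, condition: str,
                                  attended: str | None = None,
                                  min_trials: int = 1,
                                  cell_id: str = "") -> ReceptiveField:
    """One cell's receptive field from trials of one history condition.

    ``evoked_col`` is the cell's evoked response per trial. For
    prior-hit conditions, ``attended`` restricts trials to those whose
    hit streak targeted that whisker. Offsets outside the grid (CW on
    the array edge) are unsampled.
    """
    grid = session.grid
    cw_xy = grid.coordinates[cw]
    values, sampled = {}, {o: False for o in OFFSETS}
    per_offset: dict = {}
    for (t, lab), resp in zip(zip(session.trials, labels), evoked_col):
        if t.kind != "Go" or t.aborted or np.isnan(resp):
            continue
        if lab.category != condition:
            continue
        if attended is not None and lab.prior_whisker != attended:
            continue
        dx, dy = grid.offset(t.whisker, cw)
        if abs(dx) > 1 or abs(dy) > 1:
            continue
        per_offset.setdefault((dx, dy), []).append(float(resp))
    for o, vals in per_offset.items():
        if len(vals) >= min_trials:
            values[o] = float(np.mean(vals))
            sampled[o] = True
    return ReceptiveField(values=values, sampled=sampled,
                          condition=condition, cell_id=cell_id)


def rf_shift_per_cell(evoked: np.ndarray, session, labels, cells,
                      hit_conditions: tuple = ("priorGT1HitSame",
                                               "priorGT1HitDiff"),
                      min_trials: int = 1) -> dict:
    """Attention-axis RF shift for every cell, averaged over targets.

    For each cell the prior-NoGo field is compared against the field
    measured after multi-hit streaks to each sampled surround-whisker
    target; per-target shifts (equal weight) average into one value per
    cell. Cells failing the 6-of-9 coverage rule for every target are
    reported under "excluded".

    Note prior-hit-streak trials to a surround target are drawn from
    both same (current = target) and different (current != target)
    multi-hit categories, i.e. all Go trials whose streak pointed at the
    target.
    """
    grid = session.grid
    evoked = np.asarray(evoked, dtype=float)
    shifts: dict = {}
    excluded: dict = {}
    hit_cats = tuple(hit_conditions)

    for c, cell_id in enumerate(cells.cell_ids):
        cw = cells.cw[c]
        rf_nogo = receptive_field_for_condition(
            evoked[:, c], session, labels, cw, "priorNoGo",
            min_trials=min_trials, cell_id=cell_id)
        per_target = []
        reason = "no target with sufficient coverage"
        for target in grid.whiskers:
            off = grid.offset(target, cw)
            if off == (0, 0) or abs(off[0]) > 1 or abs(off[1]) > 1:
                continue
            # pool all multi-hit-streak trials whose streak targeted
            # this whisker, regardless of the current whisker
            merged = _merged_attend_field(evoked[:, c], session, labels,
                                          cw, target, hit_cats, min_trials,
                                          cell_id)
            try:
                res = rf_shift_along_attention_axis(rf_nogo, merged, off)
            except ValueError as e:
                reason = str(e)
                continue
            per_target.append(res)
        if per_target:
            mean_shift = float(np.mean([r.shift for r in per_target]))
            shifts[cell_id] = RFShiftResult(
                com_nogo=per_target[0].com_nogo,
                com_attend=per_target[0].com_attend,
                target_offset=per_target[0].target_offset,
                shift=mean_shift,
                n_targets_averaged=len(per_target))
        else:
            excluded[cell_id] = reason
    return {"shifts": shifts, "excluded": excluded}


def _merged_attend_field(evoked_col, session, labels, cw, target,
                         conditions, min_trials, cell_id) -> ReceptiveField:
    grid = session.grid
    per_offset: dict = {}
    for (t, lab), resp in zip(zip(session.trials, labels), evoked_col):
        if t.kind != "Go" or t.aborted or np.isnan(resp):
            continue
        if lab.category not in conditions or lab.prior_whisker != target:
            continue
        dx, dy = grid.offset(t.whisker, cw)
        if abs(dx) > 1 or abs(dy) > 1:
            continue
        per_offset.setdefault((dx, dy), []).append(float(resp))
    values, sampled = {}, {o: False for o in OFFSETS}
    for o, vals in per_offset.items():
        if len(vals) >= min_trials:
            values[o] = float(np.mean(vals))
            sampled[o] = True
    return ReceptiveField(values=values, sampled=sampled,
                          condition="attend", cell_id=cell_id)
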