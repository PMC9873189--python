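"""Four-stage normalization of targeted hybridization counts.

Stages, in fixed order:

1. **Positive-control normalization** — the geometric mean of the top-3
   positive-control spike-in probes measures per-sample hybridization
   efficiency; every sample is scaled so those geometric means agree.
2. **Reference-lane calibration** — a lane loaded with the same calibration
   mix on every plate corrects per-(plate, probe) biases between plates.
3. **Attenuation correction** — probes deliberately dampened with inactive
   probes (to keep high-abundance targets in dynamic range) are scaled back
   up by titration-measured factors, only in the samples that were run
   attenuated.
4. **Housekeeping normalization** — a transcript of constant expression
   corrects RNA loading differences.  Transcription-inhibited (actinomycin D)
   samples are normalized per timepoint instead, because under global
   transcription arrest the housekeeping transcript itself decays; per-
   timepoint means cancel that common trend while still removing loading.

Every factor applied is recorded in :class:`NormalizationFactors` as an audit
trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .core import ACTD_TREATMENTS, CountMatrix, DataError

logger = logging.getLogger(__name__)


@dataclass
class NormalizationFactors:
    """Audit trail of every multiplicative factor applied."""

    pc_factor_per_sample: dict[str, float] = field(default_factory=dict)
    lane_calibration: dict[tuple[str, str], float] = field(default_factory=dict)
    attenuation_applied: dict[str, float] = field(default_factory=dict)
    hk_factor_per_sample: dict[str, float] = field(default_factory=dict)
    hk_mode: str | None = None

    def merge(self, other: "NormalizationFactors") -> "NormalizationFactors":
        merged = NormalizationFactors(
            pc_factor_per_sample={**self.pc_factor_per_sample,
                                  **other.pc_factor_per_sample},
            lane_calibration={**self.lane_calibration, **other.lane_calibration},
            attenuation_applied={**self.attenuation_applied,
                                 **other.attenuation_applied},
            hk_factor_per_sample={**self.hk_factor_per_sample,
                                  **other.hk_factor_per_sample},
            hk_mode=other.hk_mode or self.hk_mode,
        )
        return merged

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit table (stage, key, factor)."""
        rows = []
        for sid, f in self.pc_factor_per_sample.items():
            rows.append(("positive_control", sid, f))
        for (plate, pid), f in self.lane_calibration.items():
            rows.append(("lane_calibration", f"{plate}:{pid}", f))
        for pid, f in self.attenuation_applied.items():
            rows.append(("attenuation", pid, f))
        for sid, f in self.hk_factor_per_sample.items():
            rows.append((f"housekeeping[{self.hk_mode}]", sid, f))
        return pd.DataFrame(rows, columns=["stage", "key", "factor"])


@dataclass(frozen=True)
class TitrationMeasurement:
    """One paired unattenuated/attenuated measurement of a probe."""

    probe_id: str
    count_unattenuated: float
    count_attenuated: float

    def __post_init__(self) -> None:
        if self.count_unattenuated <= 0 or self.count_attenuated <= 0:
            raise DataError(
                f"titration for {self.probe_id!r}: counts must be > 0"
            )


def top3_positive_controls(matrix: CountMatrix) -> list[str]:
    """The three positive-control probes with the largest mean count.

    The highest-concentration spike-ins are the least noisy, so they anchor
    the hybridization-efficiency estimate.
    """
    pcs = matrix.probes_of_class("positive_control")
    if len(pcs) < 3:
        raise DataError(
            f"positive-control normalization needs >= 3 positive-control "
            f"probes, found {len(pcs)}"
        )
    means = matrix.values.loc[[p.probe_id for p in pcs]].mean(axis=1)
    return list(means.sort_values(ascending=False).index[:3])


def positive_control_normalize(
    matrix: CountMatrix,
) -> tuple[CountMatrix, NormalizationFactors]:
    """Scale each sample so top-3 positive-control geometric means agree.

    Per sample s, g_s is the geometric mean of the top-3 positive-control
    counts; the factor f_s = mean(g)/g_s is applied to every count of s.
    """
    if matrix.stage != "raw":
        raise DataError(f"expected raw matrix, got stage {matrix.stage!r}")
    top3 = top3_positive_controls(matrix)
    pc = matrix.values.loc[top3]
    zero = pc.columns[(pc <= 0).any(axis=0)]
    if len(zero):
        raise DataError(
            f"zero positive-control count in sample(s) {list(zero)}"
        )
    g = pd.Series(gmean(pc.to_numpy(), axis=0), index=pc.columns)
    factors = g.mean() / g
    out = matrix.with_values(matrix.values * factors, "pc_normalized")
    audit = NormalizationFactors(pc_factor_per_sample=factors.to_dict())
    return out, audit


def reference_lane_calibrate(
    matrix: CountMatrix,
) -> tuple[CountMatrix, NormalizationFactors]:
    """Between-plate probe calibration from the shared reference lane.

    For each endogenous/housekeeping probe p and plate q the factor
    c(p, q) = mean_over_plates(ref count of p) / ref count of p on plate q
    is applied to all counts of p on plate q.  Requires >= 2 plates, each
    with exactly one reference-lane sample.
    """
    if matrix.stage != "pc_normalized":
        raise DataError(f"expected pc_normalized matrix, got {matrix.stage!r}")
    refs = [s for s in matrix.samples if s.is_reference_lane]
    plates = sorted({s.plate for s in matrix.samples})
    if len(plates) < 2:
        raise DataError(">=2 plates required for reference-lane calibration")
    ref_by_plate: dict[str, str] = {}
    for plate in plates:
        plate_refs = [s for s in refs if s.plate == plate]
        if len(plate_refs) != 1:
            raise DataError(
                f"plate {plate!r} must have exactly one reference lane, "
                f"found {len(plate_refs)}"
            )
        ref_by_plate[plate] = plate_refs[0].sample_id

    target_probes = [
        p.probe_id for p in matrix.probes
        if p.probe_class in ("endogenous", "housekeeping")
    ]
    ref_counts = matrix.values.loc[
        target_probes, [ref_by_plate[q] for q in plates]
    ]
    ref_counts.columns = plates

    values = matrix.values.copy()
    audit = NormalizationFactors()
    sample_plate = {s.sample_id: s.plate for s in matrix.samples}
    for pid in target_probes:
        row = ref_counts.loc[pid]
        if (row <= 0).any():
            logger.warning(
                "probe %s: zero reference-lane count; calibration factor "
                "set to 1", pid,
            )
            for q in plates:
                audit.lane_calibration[(q, pid)] = 1.0
            continue
        mean_ref = row.mean()
        for q in plates:
            c = mean_ref / row[q]
            audit.lane_calibration[(q, pid)] = float(c)
        factors = np.array(
            [audit.lane_calibration[(sample_plate[sid], pid)]
             for sid in values.columns]
        )
        values.loc[pid] = values.loc[pid].to_numpy() * factors
    return matrix.with_values(values, "calibrated"), audit


def estimate_attenuation_factor(
    titration: list[TitrationMeasurement],
) -> dict[str, float]:
    """Per-probe attenuation factor from titration pairs.

    The factor is the ratio unattenuated/attenuated; multiple pairs for the
    same probe are averaged arithmetically.  A nominal 90% count reduction
    corresponds to a factor of 10.
    """
    ratios: dict[str, list[float]] = {}
    for t in titration:
        ratios.setdefault(t.probe_id, []).append(
            t.count_unattenuated / t.count_attenuated
        )
    return {pid: float(np.mean(r)) for pid, r in ratios.items()}


def attenuation_correct(
    matrix: CountMatrix,
    factors: dict[str, float],
    attenuated_sample_ids: set[str],
) -> tuple[CountMatrix, NormalizationFactors]:
    """Multiply attenuated probes back up in the samples run attenuated."""
    if matrix.stage != "calibrated":
        raise DataError(f"expected calibrated matrix, got {matrix.stage!r}")
    attenuated_probes = [p.probe_id for p in matrix.probes if p.attenuated]
    missing = [p for p in attenuated_probes if p not in factors]
    if missing:
        raise DataError(f"attenuated probe(s) without a factor: {missing}")
    values = matrix.values.copy()
    audit = NormalizationFactors()
    col_mask = np.array(
        [sid in attenuated_sample_ids for sid in values.columns]
    )
    for pid in attenuated_probes:
        f = factors[pid]
        if f <= 0:
            raise DataError(f"attenuation factor for {pid!r} must be > 0")
        row = values.loc[pid].to_numpy()
        values.loc[pid] = np.where(col_mask, row * f, row)
        audit.attenuation_applied[pid] = float(f)
    return matrix.with_values(values, "attenuation_corrected"), audit


def default_attenuated_sample_ids(
    matrix: CountMatrix,
    treatments: frozenset[str] = frozenset({"low"}),
    rec_window_min: float = 30.0,
) -> set[str]:
    """Samples run with attenuated probes: low-iron samples plus
    iron-recovery samples within ``rec_window_min`` of iron addition."""
    out = set()
    for s in matrix.samples:
        if s.is_reference_lane:
            continue
        if s.treatment in treatments:
            out.add(s.sample_id)
        elif s.treatment == "rec" and s.time_min <= rec_window_min:
            out.add(s.sample_id)
    return out


def housekeeping_normalize(
    matrix: CountMatrix,
    hk_probe: str,
    mode: str = "global",
    group_scope: frozenset[str] | set[str] | None = None,
) -> tuple[CountMatrix, NormalizationFactors]:
    """Correct loading differences against one housekeeping transcript.

    ``global`` mode: the reference R is the arithmetic mean of housekeeping
    counts over all non-actD, non-reference samples; each in-scope sample is
    multiplied by R / hk(s).  ``per_timepoint`` mode (for the actD arms,
    where the housekeeping transcript itself decays): R_t is the mean of
    housekeeping counts over the scoped samples at timepoint t and each such
    sample is multiplied by R_t / hk(s).

    Samples outside the scope are left untouched, so the pipeline applies
    the two modes in sequence to produce one fully normalized matrix.
    """
    if matrix.stage not in ("attenuation_corrected", "fully_normalized"):
        raise DataError(
            f"expected attenuation_corrected matrix, got {matrix.stage!r}"
        )
    if hk_probe not in matrix.values.index:
        raise DataError(f"housekeeping probe {hk_probe!r} not in matrix")
    if mode not in ("global", "per_timepoint"):
        raise DataError(f"unknown housekeeping mode {mode!r}")

    hk = matrix.values.loc[hk_probe]
    audit = NormalizationFactors(hk_mode=mode)
    factors = pd.Series(1.0, index=matrix.values.columns)

    if mode == "global":
        scope_treatments = (
            frozenset(group_scope) if group_scope is not None
            else frozenset(t for t in {s.treatment for s in matrix.samples}
                           if t not in ACTD_TREATMENTS)
        )
        scoped = [
            s for s in matrix.biological_samples()
            if s.treatment in scope_treatments
        ]
        if not scoped:
            raise DataError("no samples in scope for global hk normalization")
        for s in scoped:
            if hk[s.sample_id] <= 0:
                raise DataError(
                    f"housekeeping count <= 0 in sample {s.sample_id!r}"
                )
        ref = float(np.mean([hk[s.sample_id] for s in scoped]))
        for s in scoped:
            factors[s.sample_id] = ref / hk[s.sample_id]
    else:  # per_timepoint
        scope_treatments = (
            frozenset(group_scope) if group_scope is not None
            else ACTD_TREATMENTS
        )
        scoped = [
            s for s in matrix.biological_samples()
            if s.treatment in scope_treatments
        ]
        by_time: dict[float, list] = {}
        for s in scoped:
            by_time.setdefault(s.time_min, []).append(s)
        for t, group in sorted(by_time.items()):
            for s in group:
                if hk[s.sample_id] <= 0:
                    raise DataError(
                        f"housekeeping count <= 0 in sample {s.sample_id!r}"
                    )
            if len(group) == 1:
                logger.warning(
                    "per-timepoint hk group at t=%g min has a single sample; "
                    "factor set to 1", t,
                )
                factors[group[0].sample_id] = 1.0
                continue
            ref_t = float(np.mean([hk[s.sample_id] for s in group]))
            for s in group:
                factors[s.sample_id] = ref_t / hk[s.sample_id]

    for s in matrix.samples:
        audit.hk_factor_per_sample[s.sample_id] = float(factors[s.sample_id])
    out = matrix.with_values(matrix.values * factors, "fully_normalized")
    return out, audit


@dataclass
class NormalizationConfig:
    """Configuration of the full normalization pipeline."""

    hk_probe: str
    attenuation_factors: dict[str, float] = field(default_factory=dict)
    attenuated_treatments: frozenset[str] = frozenset({"low"})
    rec_attenuation_window_min: float = 30.0
    actd_treatments: frozenset[str] = ACTD_TREATMENTS
    pool_actd_arms: bool = True


def normalize_pipeline(
    matrix: CountMatrix, config: NormalizationConfig,
) -> tuple[CountMatrix, NormalizationFactors]:
    """Run all four normalization stages in order.

    Reference-lane calibration is skipped with a warning for single-plate
    runs.  Housekeeping normalization is applied globally to the non-actD
    samples, then per-timepoint to the actD arms (pooled jointly unless
    ``pool_actd_arms`` is False).
    """
    matrix, audit = positive_control_normalize(matrix)

    plates = {s.plate for s in matrix.samples}
    refs = [s for s in matrix.samples if s.is_reference_lane]
    if len(plates) >= 2 and refs:
        matrix, a = reference_lane_calibrate(matrix)
        audit = audit.merge(a)
    else:
        logger.warning(
            "reference-lane calibration skipped (%d plate(s), %d reference "
            "lane(s))", len(plates), len(refs),
        )
        matrix = matrix.with_values(matrix.values, "calibrated")

    attenuated_ids = default_attenuated_sample_ids(
        matrix,
        treatments=config.attenuated_treatments,
        rec_window_min=config.rec_attenuation_window_min,
    )
    matrix, a = attenuation_correct(
        matrix, config.attenuation_factors, attenuated_ids
    )
    audit = audit.merge(a)

    non_actd = frozenset(
        t for t in {s.treatment for s in matrix.samples}
        if t not in config.actd_treatments
    )
    matrix, a = housekeeping_normalize(
        matrix, config.hk_probe, mode="global", group_scope=non_actd
    )
    audit = audit.merge(a)
    actd_present = {
        s.treatment for s in matrix.samples
    } & set(config.actd_treatments)
    if actd_present:
        if config.pool_actd_arms:
            scopes = [frozenset(config.actd_treatments)]
        else:
            scopes = [frozenset({t}) for t in sorted(actd_present)]
        for scope in scopes:
            matrix, a = housekeeping_normalize(
                matrix, config.hk_probe, mode="per_timepoint",
                group_scope=scope,
            )
            # global factors from the earlier call stay authoritative for
            # out-of-scope samples
            for sid, f in a.hk_factor_per_sample.items():
                if f != 1.0:
                    audit.hk_factor_per_sample[sid] = f
        audit.hk_mode = "global+per_timepoint"
    return matrix, audit
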