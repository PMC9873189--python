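"""Core data model: probe annotations, sample metadata and staged count matrices.

A targeted hybridization-counting panel (NanoString nCounter / PlexSet style)
yields a probes x samples matrix of molecule counts.  Counts move through a
fixed sequence of normalization stages; the stage tag on :class:`CountMatrix`
makes the processing state explicit and stage transitions are only allowed in
the canonical order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "positive_control", "housekeeping")
TREATMENTS = ("high", "low", "rec", "actd", "actd_fe", "dmso", "dmso_fe")
EXPERIMENTS = ("ST", "LT")

#: Canonical processing stages, in order.
STAGES = (
    "raw",
    "pc_normalized",
    "calibrated",
    "attenuation_corrected",
    "fully_normalized",
)

#: Treatments that received the transcription inhibitor actinomycin D.
ACTD_TREATMENTS = frozenset({"actd", "actd_fe"})


class DataError(ValueError):
    """Raised for malformed or contract-violating input data."""


@dataclass(frozen=True)
class ProbeInfo:
    """One probe of the panel.

    ``attenuation_factor`` is the dimensionless ratio of unattenuated to
    attenuated signal (>= 1); probes that were never attenuated carry 1.0.
    """

    probe_id: str
    gene_name: str
    probe_class: str = "endogenous"
    attenuated: bool = False
    attenuation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise DataError(
                f"probe {self.probe_id!r}: unknown probe_class {self.probe_class!r}"
            )
        if self.attenuation_factor < 1.0:
            raise DataError(
                f"probe {self.probe_id!r}: attenuation_factor must be >= 1"
            )
        if not self.attenuated and self.attenuation_factor != 1.0:
            raise DataError(
                f"probe {self.probe_id!r}: attenuation_factor must be 1.0 "
                "when the probe is not attenuated"
            )


@dataclass(frozen=True)
class SampleInfo:
    """One measured sample (a pooled lane of the run).

    ``time_min`` is minutes since the T0 addition event (iron, actD or DMSO).
    Reference-lane samples (identical calibration mix loaded on every plate)
    carry ``is_reference_lane=True`` and are excluded from biological
    analyses.
    """

    sample_id: str
    treatment: str
    time_min: float
    experiment: str
    plate: str
    lane: str
    replicate: int = 1
    rna_input_ng: float = 100.0
    is_reference_lane: bool = False

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise DataError(
                f"sample {self.sample_id!r}: unknown treatment {self.treatment!r}"
            )
        if self.experiment not in EXPERIMENTS:
            raise DataError(
                f"sample {self.sample_id!r}: unknown experiment {self.experiment!r}"
            )
        if self.time_min < 0:
            raise DataError(f"sample {self.sample_id!r}: negative time_min")
        if self.rna_input_ng <= 0:
            raise DataError(f"sample {self.sample_id!r}: rna_input_ng must be > 0")
        if self.replicate < 1:
            raise DataError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Probes x samples count table with a processing-stage tag.

    ``values`` is a DataFrame indexed by probe_id with sample_id columns, in
    the same order as ``probes`` / ``samples``.  Raw counts are nonnegative
    integers; normalized stages hold nonnegative reals.
    """

    values: pd.DataFrame
    probes: list[ProbeInfo]
    samples: list[SampleInfo]
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}")
        probe_ids = [p.probe_id for p in self.probes]
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(probe_ids)) != len(probe_ids):
            dupes = sorted({p for p in probe_ids if probe_ids.count(p) > 1})
            raise DataError(f"duplicate probe IDs: {dupes}")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise DataError(f"duplicate sample IDs: {dupes}")
        if list(self.values.index) != probe_ids or list(self.values.columns) != sample_ids:
            raise DataError(
                "values index/columns do not match probe and sample annotations"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("count matrix contains non-numeric values")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise DataError(
                f"missing/non-numeric count at probe {probe_ids[r]!r}, "
                f"sample {sample_ids[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative count at probe {probe_ids[r]!r}, sample {sample_ids[c]!r}"
            )

    # -- convenience accessors ----------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def probe(self, probe_id: str) -> ProbeInfo:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def sample(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def probes_of_class(self, probe_class: str) -> list[ProbeInfo]:
        return [p for p in self.probes if p.probe_class == probe_class]

    def biological_samples(self) -> list[SampleInfo]:
        """Samples that enter biological analyses (reference lanes excluded)."""
        return [s for s in self.samples if not s.is_reference_lane]

    # -- stage handling ------------------------------------------------------

    def with_values(self, values: pd.DataFrame, stage: str) -> "CountMatrix":
        """Return a copy with new values at ``stage``, enforcing monotone order."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise DataError(
                f"stage transition {self.stage!r} -> {stage!r} goes backwards"
            )
        return CountMatrix(
            values=values, probes=list(self.probes), samples=list(self.samples),
            stage=stage,
        )

    def subset_samples(self, keep) -> "CountMatrix":
        """Matrix restricted to samples satisfying predicate ``keep(sample)``."""
        kept = [s for s in self.samples if keep(s)]
        if not kept:
            raise DataError("sample subset is empty")
        cols = [s.sample_id for s in kept]
        return CountMatrix(
            values=self.values[cols], probes=list(self.probes), samples=kept,
            stage=self.stage,
        )

    def metadata_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        rows = [dataclasses.asdict(s) for s in self.samples]
        return pd.DataFrame(rows).set_index("sample_id")

    def probe_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(p) for p in self.probes]
        return pd.DataFrame(rows).set_index("probe_id")
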