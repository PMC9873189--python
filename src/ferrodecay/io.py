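"""Reading and writing count matrices, probe annotations and sample metadata.

Count files are delimited text (comma or tab, auto-detected from the header
line) with probe IDs in the first column and sample IDs in the header row.
A leading ``# stage=<stage>`` comment records the processing stage; files
without it are read as raw.  Probe annotations and sample metadata are CSVs
with the exact field names of :class:`~ferrodecay.core.ProbeInfo` and
:class:`~ferrodecay.core.SampleInfo`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .core import CountMatrix, DataError, ProbeInfo, SampleInfo

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    try:
        return _BOOL_MAP[str(value).strip().lower()]
    except KeyError:
        raise DataError(f"cannot interpret {value!r} as a boolean") from None


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise DataError(f"{path}: file is empty")


def _read_stage(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "stage=" in line:
                return line.split("stage=", 1)[1].strip()
    return "raw"


def read_probe_annotations(path) -> list[ProbeInfo]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#")
    required = {"probe_id", "gene_name", "probe_class", "attenuated",
                "attenuation_factor"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: probe annotation missing columns {sorted(missing)}")
    probes = [
        ProbeInfo(
            probe_id=str(r.probe_id),
            gene_name=str(r.gene_name),
            probe_class=str(r.probe_class),
            attenuated=_to_bool(r.attenuated),
            attenuation_factor=float(r.attenuation_factor),
        )
        for r in df.itertuples()
    ]
    ids = [p.probe_id for p in probes]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate probe IDs in annotation")
    return probes


def read_sample_metadata(path) -> list[SampleInfo]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#")
    required = {"sample_id", "treatment", "time_min", "experiment", "plate",
                "lane", "replicate", "rna_input_ng", "is_reference_lane"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: sample metadata missing columns {sorted(missing)}")
    return [
        SampleInfo(
            sample_id=str(r.sample_id),
            treatment=str(r.treatment),
            time_min=float(r.time_min),
            experiment=str(r.experiment),
            plate=str(r.plate),
            lane=str(r.lane),
            replicate=int(r.replicate),
            rna_input_ng=float(r.rna_input_ng),
            is_reference_lane=_to_bool(r.is_reference_lane),
        )
        for r in df.itertuples()
    ]


def read_count_matrix(path, probe_annotation_path, metadata_path) -> CountMatrix:
    """Read a delimited count table plus its probe and sample annotations.

    Row/column order is preserved from the count file.  Every probe and
    sample in the count file must be covered by the annotations; offenders
    are named in the error.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", index_col=0,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: malformed count file ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataError(f"{path}: duplicate probe IDs {dupes}")

    # Coerce counts to numbers, reporting the offending cell.
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.isna().stack()
        probe, sample = bad[bad].index[0]
        raise DataError(
            f"{path}: non-numeric count at probe {probe!r}, sample {sample!r}"
        )
    if (values.to_numpy() < 0).any():
        bad = (values < 0).stack()
        probe, sample = bad[bad].index[0]
        raise DataError(
            f"{path}: negative count at probe {probe!r}, sample {sample!r}"
        )

    probes_by_id = {p.probe_id: p for p in read_probe_annotations(probe_annotation_path)}
    samples_by_id = {s.sample_id: s for s in read_sample_metadata(metadata_path)}
    missing_probes = [p for p in values.index if p not in probes_by_id]
    if missing_probes:
        raise DataError(f"probes missing from annotation: {missing_probes}")
    missing_samples = [s for s in values.columns if s not in samples_by_id]
    if missing_samples:
        raise DataError(f"samples missing from metadata: {missing_samples}")

    return CountMatrix(
        values=values,
        probes=[probes_by_id[p] for p in values.index],
        samples=[samples_by_id[s] for s in values.columns],
        stage=_read_stage(path),
    )


def write_counts(matrix: CountMatrix, path) -> None:
    """Write a count matrix as delimited text with a stage comment line.

    ``read_count_matrix(write_counts(m))`` is the identity on values to full
    float precision (Python repr round-trip).
    """
    if not matrix.samples:
        raise DataError("no samples")
    if not matrix.probes:
        raise DataError("no probes")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# stage={matrix.stage}\n")
        matrix.values.to_csv(fh, index_label="probe_id")


def write_probe_annotations(probes: list[ProbeInfo], path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in probes]).to_csv(path, index=False)


def write_sample_metadata(samples: list[SampleInfo], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(path, index=False)


def read_titration(path) -> pd.DataFrame:
    """Titration table: probe_id, count_unattenuated, count_attenuated."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), comment="#")
    required = {"probe_id", "count_unattenuated", "count_attenuated"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: titration table missing columns {sorted(missing)}")
    return df
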