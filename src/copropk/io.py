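"""Dataset I/O: a documented CSV dialect for the longitudinal event data.

Columns (NONMEM-flavoured long format):

    ID      subject identifier (int)
    OCC     occasion label (str, e.g. OCC1)
    TIME    occasion-local time in hours; the dose is at t=0, pre-dose
            samples carry times <= 0 (urine collection starts at -7 h)
    AMT     dose amount (mg) on dose rows, empty otherwise
    CMT     compartment code (see copropk.trial.CMT_CODES)
    EVID    1 for dose rows, 0 for observations
    DV      observed value; units per stream (RIF/RSV plasma uM, CPI plasma
            nM, urine amounts nmol); urine rows hold the amount collected
            over the interval ending at TIME
    MDV     1 where DV is missing
    STREAM  observation/dose stream name

A commented header block records the stream units so that files cannot be
re-read with silently different unit conventions.
"""

from __future__ import annotations

import pandas as pd

from .trial import DATASET_COLUMNS, STREAM_UNITS

_HEADER_PREFIX = "# units:"


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a dataset with its unit header; lossless round-trip."""
    missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset is missing columns {missing}")
    with open(path, "w") as fh:
        for stream, unit in STREAM_UNITS.items():
            fh.write(f"{_HEADER_PREFIX} {stream}={unit}\n")
        dataset.to_csv(fh, index=False, columns=DATASET_COLUMNS)


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset written by :func:`write_dataset`, validating units,
    required columns, stream names and per-subject time ordering."""
    units = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith(_HEADER_PREFIX):
                k, _, v = line[len(_HEADER_PREFIX):].strip().partition("=")
                units[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} is missing columns {missing}")
    unknown = set(df["STREAM"].unique()) - set(STREAM_UNITS)
    if unknown:
        raise ValueError(f"unknown streams in {path}: {sorted(unknown)}")
    for stream, unit in units.items():
        if stream in STREAM_UNITS and unit != STREAM_UNITS[stream]:
            raise ValueError(
                f"unit mismatch for {stream}: file says {unit!r}, "
                f"expected {STREAM_UNITS[stream]!r}")
    obs = df[df["EVID"] == 0]
    bad = (obs.groupby(["ID", "OCC", "STREAM"])["TIME"]
              .apply(lambda t: bool((t.diff().dropna() < 0).any())))
    if bad.any():
        keys = [k for k, v in bad.items() if v][:3]
        raise ValueError(f"non-monotone observation times for {keys} ...")
    df["OCC"] = df["OCC"].astype(str)
    return df
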