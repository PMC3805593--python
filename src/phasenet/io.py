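"""Plain-text persistence for cohorts, matrices and tidy tables.

The native on-disk formats are tab-delimited text: association matrices
as square tables with a channel-label header, cohorts as one
``<subject>.tsv`` signal file per subject plus a shared trial-metadata
table.  EDF export is available when :mod:`pyedflib` is installed, but
nothing in the pipeline requires it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from phasenet.montage import Montage
from phasenet.preprocess import EpochSet

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "read_cohort",
    "write_cohort_edf",
    "write_table",
    "read_table",
]

_FLOAT_FMT = "%.12g"


def write_matrix(path, matrix: np.ndarray, labels) -> None:
    """Square delimited matrix with a header row of channel labels.

    Row ``i`` corresponds to ``labels[i]``, matching the column order.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in matrix:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    with open(path) as fh:
        labels = tuple(fh.readline().rstrip("\n").split("\t"))
        matrix = np.loadtxt(fh, delimiter="\t")
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError(f"{path}: matrix shape {matrix.shape} does not match header")
    return matrix, labels


def write_table(path, table: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cohort(directory, cohort: list[EpochSet]) -> None:
    """Persist a cohort as per-subject signal files plus one metadata table.

    ``<subject>.tsv`` holds ``trial`` and ``channel`` key columns
    followed by one column per sample; ``metadata.tsv`` has one row per
    (subject, trial) with group, block, hand, angle and correctness.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for es in cohort:
        n_trials, n_chan, n_samp = es.data.shape
        with open(directory / f"{es.subject_id}.tsv", "w") as fh:
            header = ["trial", "channel"] + [f"s{i}" for i in range(n_samp)]
            fh.write("\t".join(header) + "\n")
            for t in range(n_trials):
                for c, label in enumerate(es.montage.labels):
                    vals = "\t".join(_FLOAT_FMT % v for v in es.data[t, c])
                    fh.write(f"{t}\t{label}\t{vals}\n")
        meta = es.meta.copy()
        meta.insert(0, "subject", es.subject_id)
        meta.insert(1, "group", es.group)
        meta["fs"] = es.fs
        meta_rows.append(meta)
    write_table(directory / "metadata.tsv", pd.concat(meta_rows, ignore_index=True))


def read_cohort(directory, montage: Montage) -> list[EpochSet]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    meta_all = read_table(directory / "metadata.tsv")
    cohort = []
    for sid, meta in meta_all.groupby("subject", sort=False):
        raw = pd.read_csv(directory / f"{sid}.tsv", sep="\t")
        n_trials = int(raw["trial"].max()) + 1
        n_samp = raw.shape[1] - 2
        data = np.empty((n_trials, montage.n_channels, n_samp))
        label_idx = {lab: i for i, lab in enumerate(montage.labels)}
        samples = raw.iloc[:, 2:].to_numpy(float)
        for row, (t, lab) in enumerate(zip(raw["trial"], raw["channel"])):
            data[int(t), label_idx[lab]] = samples[row]
        meta = meta.reset_index(drop=True)
        cohort.append(EpochSet(
            data=data, fs=float(meta["fs"].iloc[0]), montage=montage,
            meta=meta[["hand", "angle", "correct"]].assign(
                block=meta.get("block", 0)),
            subject_id=str(sid), group=str(meta["group"].iloc[0]),
        ))
    return cohort


def write_cohort_edf(directory, cohort: list[EpochSet]) -> None:
    """EDF export (one file per subject); requires ``pyedflib``."""
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF export requires the optional dependency pyedflib "
            "(pip install phasenet[edf]); the delimited-text writer "
            "write_cohort() needs no extra packages") from exc
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for es in cohort:  # pragma: no cover - optional dependency
        n_trials, n_chan, n_samp = es.data.shape
        flat = es.data.transpose(1, 0, 2).reshape(n_chan, -1)
        with pyedflib.EdfWriter(str(directory / f"{es.subject_id}.edf"),
                                n_chan) as writer:
            for c, label in enumerate(es.montage.labels):
                writer.setSignalHeader(c, {
                    "label": label, "dimension": "uV",
                    "sample_frequency": es.fs,
                    "physical_min": float(flat[c].min()),
                    "physical_max": float(flat[c].max()) + 1e-9,
                    "digital_min": -32768, "digital_max": 32767,
                    "transducer": "", "prefilter": "",
                })
            writer.writeSamples(list(flat))
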