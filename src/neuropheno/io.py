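"""Readers and writers for the standard on-disk formats.

Spike tables and fluorescence traces travel as CSV, raw voltage as HDF5
(``/voltage`` electrode × sample plus ``/sampling_rate``), images as
multi-page TIFF, count matrices as MatrixMarket MTX with features/
barcodes TSV and a metadata CSV, and gene sets as GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse


# ------------------------------------------------------------------- spikes


def write_spike_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_spike_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_recording(rec: dict, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=rec["voltage"], dtype="f4")
        f.create_dataset("sampling_rate", data=float(rec["sampling_rate"]))


def read_recording(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            "voltage": f["voltage"][()].astype(float),
            "sampling_rate": float(f["sampling_rate"][()]),
        }


# ------------------------------------------------------------------- traces


def write_traces(traces: pd.DataFrame, path: str | Path) -> None:
    """Long-format CSV (roi, frame, F); frame rate goes in a header row."""
    long = traces.stack().rename("F").reset_index()
    long.columns = ["roi", "frame", "F"]
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={traces.attrs.get('frame_rate', 'nan')}\n")
        long.to_csv(fh, index=False)


def read_traces(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip()
        long = pd.read_csv(fh)
    wide = long.pivot(index="roi", columns="frame", values="F")
    wide.columns.name = None
    if header.startswith("# frame_rate="):
        wide.attrs["frame_rate"] = float(header.split("=", 1)[1])
    return wide


# -------------------------------------------------------------------- image


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(
        path, np.asarray(image, dtype=np.float32), photometric="minisblack"
    )


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


# ------------------------------------------------------------------- counts


def write_counts(
    counts: pd.DataFrame, meta: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(counts.columns).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta.to_csv(outdir / "meta.csv", index_label="cell")


def read_counts(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    outdir = Path(outdir)
    m = spio.mmread(outdir / "matrix.mtx").toarray().astype(np.int64)
    genes = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0]
    counts = pd.DataFrame(m, index=genes.tolist(), columns=cells.tolist())
    meta = pd.read_csv(outdir / "meta.csv", index_col="cell")
    return counts, meta


# ---------------------------------------------------------------------- GMT


def write_gmt(signatures: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out


# ------------------------------------------------------------- ground truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Serialize a ground-truth dict to JSON (arrays/frames inlined)."""

    def conv(v):
        if isinstance(v, pd.DataFrame):
            return v.to_dict(orient="list")
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating, np.bool_)):
            return v.item()
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if hasattr(v, "__dataclass_fields__"):
            return {k: conv(getattr(v, k)) for k in v.__dataclass_fields__}
        return v

    with open(path, "w") as fh:
        json.dump(conv(truth), fh)
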