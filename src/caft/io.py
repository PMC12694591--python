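"""Readers and writers for count tables, metadata and results.

Count tables are TSV/CSV (taxa as rows by default — the dominant OTU
table convention — with an orientation flag) or BIOM.  Both BIOM
dialects are handled: the JSON (format 1.0) dialect directly, and the
HDF5 (format 2.x) dialect through :mod:`h5py` by reading the CSR
matrix stored under the ``observation`` group.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .censoring import CountTable
from .exceptions import CaftError

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_results",
]

log = logging.getLogger("caft")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _is_hdf5(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(8) == b"\x89HDF\r\n\x1a\n"


def _read_biom_json(path: Path):
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[r, c] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    return mat, obs_ids, sample_ids


def _read_biom_hdf5(path: Path):
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        data = fh["observation/matrix/data"][:]
        indices = fh["observation/matrix/indices"][:]
        indptr = fh["observation/matrix/indptr"][:]
        obs_ids = [i.decode() if isinstance(i, bytes) else i for i in fh["observation/ids"][:]]
        sample_ids = [i.decode() if isinstance(i, bytes) else i for i in fh["sample/ids"][:]]
    mat = sparse.csr_matrix((data, indices, indptr), shape=(len(obs_ids), len(sample_ids)))
    return mat.toarray(), obs_ids, sample_ids


def read_count_table(path, taxa_as_rows: bool = True) -> CountTable:
    """Read a TSV/CSV or BIOM count table into a :class:`CountTable`.

    For delimited files the first column holds feature ids and the
    header holds the other axis's ids; ``taxa_as_rows`` names the row
    axis.  BIOM files are always observations (taxa) by samples.
    Non-integer or negative entries are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".biom":
        mat, obs_ids, sample_ids = (
            _read_biom_hdf5(path) if _is_hdf5(path) else _read_biom_json(path)
        )
        df = pd.DataFrame(mat, index=obs_ids, columns=sample_ids)
        taxa_as_rows = True
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise CaftError(f"duplicate feature id in {path.name}: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise CaftError(f"duplicate sample id in {path.name}: {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CaftError(f"{path.name}: non-numeric entries in count table")
    if np.any(values < 0) or np.any(values != np.round(values)):
        raise CaftError(f"{path.name}: counts must be nonnegative integers")
    df = df.astype(np.int64)
    return CountTable.from_dataframe(df, taxa_as_rows=taxa_as_rows)


def write_count_table(table: CountTable, path, taxa_as_rows: bool = True) -> None:
    path = Path(path)
    table.to_dataframe(taxa_as_rows=taxa_as_rows).to_csv(path, sep=_sep_for(path))


def read_metadata(path, sample_id_column: str) -> pd.DataFrame:
    """Read a TSV/CSV metadata table indexed by the sample-id column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if sample_id_column not in df.columns:
        raise CaftError(f"{path.name}: missing sample id column {sample_id_column!r}")
    df[sample_id_column] = df[sample_id_column].astype(str)
    if df[sample_id_column].duplicated().any():
        raise CaftError(f"{path.name}: duplicated sample ids")
    return df.set_index(sample_id_column)


def write_results(results, prefix) -> None:
    """Write the per-taxon table (TSV) and a JSON run-metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    results.table.to_csv(f"{prefix}.results.tsv", sep="\t", index=False)
    sidecar = {
        "interest": list(results.interest),
        "adjust": list(results.adjust),
        "reference_log_abundance_scale": np.asarray(results.reference).tolist(),
        "fdr_threshold": results.config.fdr_threshold,
        "min_library": results.config.min_library,
        "min_presence_frac": results.config.min_presence_frac,
        **results.metadata,
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    log.info("wrote %s.results.tsv and %s.meta.json", prefix, prefix)
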