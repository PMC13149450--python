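"""Readers and writers for the formats the pipeline touches.

MatrixMarket (MTX triplet) + gene/barcode lists or dense TSV for expression,
TSV for coordinates / fractions / survival, GMT for gene sets, JSON + TSV
for results. All readers validate and reject rather than silently coerce;
writer/reader pairs round-trip losslessly at declared precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    FormatError,
    FractionTable,
    GeneSet,
    SpotLattice,
    SurvivalTable,
)

log = logging.getLogger(__name__)


# ------------------------------------------------------------ expression

def read_expression_mtx(
    path_matrix: str | Path, path_genes: str | Path, path_barcodes: str | Path
) -> ExpressionMatrix:
    """Read a genes x spots MTX triplet with sidecar gene/barcode lists."""
    try:
        mat = scipy.io.mmread(str(path_matrix))
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path_matrix}: invalid MatrixMarket file ({exc})") from exc
    mat = scipy.sparse.coo_matrix(mat)
    genes = _read_id_list(path_genes)
    barcodes = _read_id_list(path_barcodes)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{path_genes}: {len(genes)} genes but matrix has {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{path_barcodes}: {len(barcodes)} barcodes but matrix has "
            f"{mat.shape[1]} columns"
        )
    dense = np.asarray(mat.todense(), dtype=float)
    if np.any(dense < 0):
        raise FormatError(f"{path_matrix}: negative entries")
    return ExpressionMatrix(genes, barcodes, dense, state="raw_counts")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a dense genes x spots TSV (first column gene ids, header spot ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty table")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise FormatError(f"{path}: negative entries")
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], vals, state="raw_counts"
    )


def write_expression_mtx(
    expr: ExpressionMatrix, path_matrix: str | Path, path_genes: str | Path,
    path_barcodes: str | Path,
) -> None:
    sp = scipy.sparse.coo_matrix(expr.values)
    scipy.io.mmwrite(str(path_matrix), sp)
    Path(path_genes).write_text("".join(f"{g}\n" for g in expr.gene_ids))
    Path(path_barcodes).write_text("".join(f"{s}\n" for s in expr.spot_ids))


def _read_id_list(path: str | Path) -> list[str]:
    ids = [ln.split("\t")[0].strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate ids")
    return ids


# ----------------------------------------------------------- coordinates

def read_coords(path: str | Path) -> SpotLattice:
    """TSV with columns spot_id, x, y."""
    df = pd.read_csv(path, sep="\t")
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return SpotLattice(
        [str(s) for s in df["spot_id"]], df[["x", "y"]].to_numpy(dtype=float)
    )


def write_coords(lattice: SpotLattice, path: str | Path) -> None:
    pd.DataFrame(
        {"spot_id": lattice.spot_ids, "x": lattice.coords[:, 0], "y": lattice.coords[:, 1]}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ------------------------------------------------------------- fractions

def read_fractions(path: str | Path) -> FractionTable:
    """TSV with spot_id column plus one column per cell type.

    Rows whose sum deviates from 1 by at most 1e-3 are renormalized;
    larger deviations are format errors.
    """
    df = pd.read_csv(path, sep="\t")
    if "spot_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'spot_id'")
    types = [c for c in df.columns if c != "spot_id"]
    vals = df[types].to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        raise FormatError(
            f"{path}: {int(bad.sum())} rows violate the simplex beyond 1e-3 "
            f"(first at line {int(np.argmax(bad)) + 2})"
        )
    fix = np.abs(sums - 1.0) > 1e-6
    if fix.any():
        log.warning("%s: renormalizing %d rows within tolerance", path, int(fix.sum()))
        vals[fix] = vals[fix] / sums[fix, None]
    return FractionTable([str(s) for s in df["spot_id"]], types, vals)


def write_fractions(fractions: FractionTable, path: str | Path) -> None:
    df = pd.DataFrame(fractions.values, columns=fractions.cell_types)
    df.insert(0, "spot_id", fractions.spot_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ------------------------------------------------------------------- gmt

def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then gene symbols."""
    sets = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs >= 3 fields")
        sets.append(GeneSet(fields[0], [g for g in fields[2:] if g]))
    return sets


# -------------------------------------------------------------- survival

def read_survival(path: str | Path) -> SurvivalTable:
    """TSV with columns sample_id, time, event (event 1 = death observed)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    time = df["time"].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise FormatError(f"{path}: nonpositive survival time")
    return SurvivalTable(
        [str(s) for s in df["sample_id"]], time, df["event"].to_numpy(dtype=bool)
    )


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "time": table.time,
            "event": table.event.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# --------------------------------------------------------------- results

def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a result bundle.

    Writes global statistics JSON, per-spot LISA TSV, zone-profile TSV,
    TEC/NEC comparison TSV, and run metadata (seed, config hash, versions).
    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "global" in results:
        p = out / "global_stats.json"
        p.write_text(json.dumps(results["global"], indent=2, default=_json_default) + "\n")
        written["global"] = p
    for key, name in (
        ("lisa", "lisa.tsv"),
        ("zone_profile", "zone_profile.tsv"),
        ("tec_nec", "tec_nec.tsv"),
        ("spots", "spots.tsv"),
    ):
        if key in results:
            p = out / name
            df = results[key]
            df.to_csv(p, sep="\t", index=False, float_format="%.12g")
            written[key] = p
    if "metadata" in results:
        meta = dict(results["metadata"])
        meta.setdefault("config_hash", config_hash(meta.get("config", {})))
        meta["versions"] = _versions()
        p = out / "run_metadata.json"
        p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
        written["metadata"] = p
    return written


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return str(obj)
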