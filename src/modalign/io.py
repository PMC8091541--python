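"""Readers/writers for the supported on-disk formats and the shared run path.

Formats: CSV/TSV (observations x features, first column = observation id,
header row = feature names), Matrix Market with companion ``<base>_rows.txt``
and ``<base>_cols.txt`` name files, HDF5-backed single-cell containers
(``.h5ad``), and two-column sequence TSV (cell_id, sequence).

The command-line interface is a thin wrapper over :func:`run`, which both the
CLI and the Python API call, so identical configurations produce byte-identical
outputs regardless of the entry point.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import __version__
from . import api
from . import preprocessing as prep
from .builders import encode_cdr3
from .distance import DEFAULT_PAIR_COUNT, PrimaryModality, SecondaryModality
from .exceptions import InvalidInputError
from .qp import DEFAULT_Q, WeightSolution

_MATRIX_FORMATS = ("csv", "tsv", "mtx", "h5ad")
_FORMATS = _MATRIX_FORMATS + ("sequence-tsv",)
_SUFFIX_FORMAT = {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx", ".h5ad": "h5ad"}


@dataclass
class ModalityTable:
    """A row-identified payload as read from disk."""

    ids: list[str]
    columns: list[str] | None
    values: np.ndarray | scipy.sparse.spmatrix
    kind: str = "matrix"  # "matrix" or "sequence"


def infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix not in _SUFFIX_FORMAT:
        raise InvalidInputError(
            f"cannot infer format from {path!r}; declare one of {_FORMATS}"
        )
    return _SUFFIX_FORMAT[suffix]


def read_modality(path: str | Path, format: str | None = None) -> ModalityTable:
    """Read a modality payload with row identifiers.

    Sparse MTX input stays sparse until a reduction densifies or consumes it.
    """
    path = Path(path)
    fmt = format or infer_format(path)
    if fmt not in _FORMATS:
        raise InvalidInputError(f"unknown format {fmt!r}; choose from {_FORMATS}")
    if not path.exists():
        raise InvalidInputError(f"file not found: {path}")
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        return ModalityTable(
            ids=[str(i) for i in df.index],
            columns=[str(c) for c in df.columns],
            values=df.to_numpy(),
        )
    if fmt == "mtx":
        base = path.with_suffix("")
        rows_file = Path(f"{base}_rows.txt")
        cols_file = Path(f"{base}_cols.txt")
        for companion in (rows_file, cols_file):
            if not companion.exists():
                raise InvalidInputError(
                    f"MTX input {path} is missing its companion name file "
                    f"{companion} (one identifier per line)"
                )
        mat = scipy.io.mmread(path).tocsr()
        ids = rows_file.read_text().splitlines()
        cols = cols_file.read_text().splitlines()
        if mat.shape != (len(ids), len(cols)):
            raise InvalidInputError(
                f"MTX shape {mat.shape} disagrees with name files "
                f"({len(ids)} rows, {len(cols)} cols)"
            )
        return ModalityTable(ids=ids, columns=cols, values=mat)
    if fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        return ModalityTable(
            ids=[str(i) for i in adata.obs_names],
            columns=[str(c) for c in adata.var_names],
            values=adata.X,
        )
    # sequence-tsv
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise InvalidInputError(
            f"sequence TSV must have exactly two columns (cell_id, sequence); "
            f"got {df.shape[1]}"
        )
    return ModalityTable(
        ids=[str(i) for i in df.iloc[:, 0]],
        columns=None,
        values=df.iloc[:, 1].to_numpy(dtype=object),
        kind="sequence",
    )


def write_matrix(path: str | Path, ids, columns, values) -> None:
    """Write an observations x features table in the CSV/TSV dialect of read_modality."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame(np.asarray(values), index=list(ids), columns=list(columns))
    df.to_csv(path, sep=sep, index_label="cell_id")


def read_spatial(path: str | Path):
    """Read a spatial TSV (cell_id, x, y[, cell_type]).

    Returns ``(ids, xy, cell_types)`` with ``cell_types`` None when absent.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] not in (3, 4):
        raise InvalidInputError(
            f"spatial TSV must have columns cell_id, x, y[, cell_type]; "
            f"got {df.shape[1]} columns"
        )
    ids = [str(i) for i in df.iloc[:, 0]]
    xy = df.iloc[:, 1:3].to_numpy(dtype=float)
    cell_types = (
        df.iloc[:, 3].astype(str).to_numpy() if df.shape[1] == 4 else None
    )
    return ids, xy, cell_types


def write_density(path: str | Path, ids, values) -> None:
    """Write per-cell density scores as TSV (cell_id, density)."""
    pd.DataFrame({"cell_id": list(ids), "density": np.asarray(values, float)}).to_csv(
        path, sep="\t", index=False
    )


def align_to(primary_ids: list[str], table: ModalityTable, name: str) -> ModalityTable:
    """Reorder a table's rows to match the primary's observation identifiers."""
    pos = {i: p for p, i in enumerate(table.ids)}
    missing = [i for i in primary_ids if i not in pos]
    if missing:
        raise InvalidInputError(
            f"modality {name!r} is missing {len(missing)} observation(s) present "
            f"in the primary; first offenders: {missing[:5]}"
        )
    order = np.array([pos[i] for i in primary_ids])
    return ModalityTable(
        ids=list(primary_ids),
        columns=table.columns,
        values=table.values[order],
        kind=table.kind,
    )


@dataclass
class SecondarySpec:
    path: str
    metric: str
    gamma: float = 1.0
    format: str | None = None
    target: str | None = None


@dataclass
class RunConfig:
    """Everything needed to reproduce a run from the shell or the API."""

    primary_path: str
    secondaries: list[SecondarySpec]
    primary_format: str | None = None
    primary_metric: str = "euclidean_sq"
    s_values: tuple = (0.99,)
    q: float = DEFAULT_Q
    pair_count: int = DEFAULT_PAIR_COUNT
    seed: int = 0
    reduce_method: str = "none"
    reduce_components: int = 50
    max_seq_len: int = 20
    outdir: str = "modalign_out"


def _canonical_config(config: RunConfig) -> dict:
    d = asdict(config)
    d["s_values"] = [float(s) for s in config.s_values]
    return d


def _load_primary(config: RunConfig) -> tuple[PrimaryModality, list[str], np.ndarray | None]:
    fmt = config.primary_format or infer_format(config.primary_path)
    table = read_modality(config.primary_path, fmt)
    loadings = None
    if table.kind == "sequence" or fmt == "sequence-tsv":
        enc = encode_cdr3(list(table.values), max_len=config.max_seq_len)
        primary = PrimaryModality(
            X=enc.positional,
            feature_names=[f"pos_{i + 1}" for i in range(config.max_seq_len)],
            metric_kind="hamming",
        )
        return primary, table.ids, None
    values = table.values
    names = table.columns
    if config.reduce_method != "none":
        spec = prep.ReductionSpec(config.reduce_method, config.reduce_components)
        values, loadings = prep.reduce(values, spec, seed=config.seed)
        names = [f"{config.reduce_method}_{i}" for i in range(values.shape[1])]
    elif scipy.sparse.issparse(values):
        values = np.asarray(values.todense())
    primary = PrimaryModality(
        X=np.asarray(values, dtype=float),
        feature_names=list(names),
        metric_kind=config.primary_metric,
    )
    return primary, table.ids, loadings


def _load_secondary(spec: SecondarySpec, primary_ids: list[str]) -> SecondaryModality:
    table = read_modality(spec.path, spec.format)
    table = align_to(primary_ids, table, name=spec.path)
    values = table.values
    if scipy.sparse.issparse(values):
        values = np.asarray(values.todense())
    if spec.metric in ("absolute_diff", "categorical_mismatch"):
        values = np.asarray(values)
        if values.ndim == 2:
            if values.shape[1] != 1:
                raise InvalidInputError(
                    f"{spec.path}: metric {spec.metric!r} needs a single column, "
                    f"got {values.shape[1]}"
                )
            values = values[:, 0]
        if spec.metric == "categorical_mismatch" and spec.target is not None:
            values = values == type(values.flat[0])(spec.target)
    if table.kind == "sequence":
        if spec.metric != "hamming":
            raise InvalidInputError(
                f"{spec.path}: sequence payloads require the hamming metric"
            )
        values = encode_cdr3(list(values)).positional
    return SecondaryModality(
        payload=values,
        metric_kind=spec.metric,
        gamma=spec.gamma,
        name=Path(spec.path).name,
    )


def _weights_frame(names, weight, normalized) -> pd.DataFrame:
    order = np.argsort(-np.asarray(normalized), kind="stable")
    rank = np.empty(len(names), dtype=int)
    rank[order] = np.arange(1, len(names) + 1)
    return pd.DataFrame(
        {
            "feature_name": list(names),
            "weight": np.asarray(weight, dtype=float),
            "normalized_weight": np.asarray(normalized, dtype=float),
            "rank": rank,
        }
    )


def _json_safe(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_json_safe(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(x) for x in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run(config: RunConfig) -> tuple[object, dict[str, Path]]:
    """Execute a full fit (or ensemble) from a run configuration.

    Writes ``weights.tsv``, ``metadata.json``, ``feasibility.tsv`` and, for a
    single-``s`` fit, ``transformed.tsv`` into ``config.outdir``.  Returns the
    result object and the paths written.  Fully deterministic for a fixed
    configuration and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    primary, ids, loadings = _load_primary(config)
    # drop constant features here so the transformed output matches the fit space
    primary = primary.drop_constant_features()
    secondaries = [_load_secondary(s, ids) for s in config.secondaries]
    fit_config = api.FitConfig(
        s_values=tuple(config.s_values),
        pair_count=config.pair_count,
        seed=config.seed,
        q=config.q,
    )
    conf_dict = _canonical_config(config)
    conf_json = json.dumps(conf_dict, sort_keys=True)
    meta = {
        "package": "modalign",
        "version": __version__,
        "config": conf_dict,
        "config_hash": hashlib.sha256(conf_json.encode()).hexdigest(),
        "seed": config.seed,
        "pair_count_requested": config.pair_count,
        "q": config.q,
        "s_values": list(config.s_values),
    }
    paths: dict[str, Path] = {}
    ensemble_mode = len(config.s_values) > 1
    if ensemble_mode:
        result = api.run_ensemble(primary, secondaries, fit_config)
        wf = _weights_frame(
            result.feature_names, result.raw_mean_weights, result.mean_weights
        )
        meta.update(
            {
                "mode": "ensemble",
                "s_values_used": result.s_values_used,
                "s_values_dropped": result.s_values_dropped,
                "chosen_per_run": [list(s.chosen) for s in result.solutions],
                "achieved_corr_per_run": [
                    list(s.achieved_corr) for s in result.solutions
                ],
            }
        )
        feas_rows = []
        for s_val, sol in zip(result.s_values_used, result.solutions):
            for row in sol.feasibility_table:
                feas_rows.append({"s": s_val, **row})
    else:
        solution: WeightSolution = api.fit(primary, secondaries, fit_config)
        result = solution
        wf = _weights_frame(solution.feature_names, solution.w, solution.w_mean1)
        meta.update(
            {
                "mode": "fit",
                "chosen": list(solution.chosen),
                "achieved_corr": list(solution.achieved_corr),
                "objective_value": solution.objective_value,
                "n_features_fit": len(solution.feature_names),
            }
        )
        feas_rows = list(solution.feasibility_table)
        if primary.metric_kind == "euclidean_sq":
            # symbolic (hamming) primaries have no meaningful scaled coordinates
            transformed = api.transform(primary.X, solution)
            paths["transformed"] = outdir / "transformed.tsv"
            write_matrix(paths["transformed"], ids, primary.feature_names, transformed)

    paths["weights"] = outdir / "weights.tsv"
    wf.to_csv(paths["weights"], sep="\t", index=False)
    paths["feasibility"] = outdir / "feasibility.tsv"
    pd.DataFrame(feas_rows).to_csv(paths["feasibility"], sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.json"
    paths["metadata"].write_text(
        json.dumps(_json_safe(meta), sort_keys=True, indent=2) + "\n"
    )
    if loadings is not None:
        paths["loadings"] = outdir / "loadings.tsv"
        pd.DataFrame(loadings).to_csv(paths["loadings"], sep="\t", index=False)
    return result, paths
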