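"""File I/O: labeled-matrix CSV dialect, catalogs, and the analysis writer.

The labeled-matrix CSV dialect is: first row = blank corner cell followed
by the factor_ids; each subsequent row = a factor_id followed by n numeric
cells; UTF-8 with "." as the decimal separator. Matrices round-trip at
full floating precision; display rounding (half away from zero) is applied
only when a precision is requested.
"""

from __future__ import annotations

import dataclasses
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from dematelkit.catalog import FactorCatalog
from dematelkit.core import AnalysisResult
from dematelkit.errors import ValidationError
from dematelkit.network import build_network, export_network


def display_round(x: float, precision: int) -> float:
    """Round half away from zero to ``precision`` decimals (presentation only)."""
    q = Decimal(1).scaleb(-precision)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float, precision: int | None) -> str:
    if precision is None:
        return repr(float(x))
    return f"{display_round(x, precision):.{precision}f}"


def write_matrix_csv(
    values: np.ndarray,
    catalog: FactorCatalog,
    path: str | Path,
    *,
    precision: int | None = None,
) -> None:
    """Write a labeled square matrix in the labeled-matrix CSV dialect."""
    values = np.asarray(values, dtype=float)
    if values.shape != (catalog.n, catalog.n):
        raise ValidationError(
            f"matrix shape {values.shape} does not match catalog with {catalog.n} factors"
        )
    lines = ["," + ",".join(catalog.ids)]
    for i, fid in enumerate(catalog.ids):
        lines.append(fid + "," + ",".join(_fmt(v, precision) for v in values[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix_csv(
    path: str | Path, catalog: FactorCatalog | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labeled-matrix CSV; returns (values, labels) in catalog order.

    If ``catalog`` is given, row/column labels are verified against it:
    a permuted-but-complete label set is reordered into catalog order; a
    set-wise mismatch is an error naming the missing/extra labels.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"{path}: cannot parse labeled-matrix CSV: {exc}") from exc
    row_labels = tuple(str(x) for x in df.index)
    col_labels = tuple(str(x) for x in df.columns)
    if set(row_labels) != set(col_labels):
        raise ValidationError(f"{path}: row labels and column labels differ as sets")
    if len(set(row_labels)) != len(row_labels):
        raise ValidationError(f"{path}: duplicate labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        for lineno, row in enumerate(df.itertuples(index=True), start=2):
            for cell in row[1:]:
                try:
                    float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}"
                    ) from exc
        raise ValidationError(f"{path}: non-numeric data") from exc

    if catalog is None:
        # align columns to row order
        order = [col_labels.index(lab) for lab in row_labels]
        return values[:, order], row_labels

    missing = set(catalog.ids) - set(row_labels)
    extra = set(row_labels) - set(catalog.ids)
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing labels {sorted(missing)}")
        if extra:
            parts.append(f"unexpected labels {sorted(extra)}")
        raise ValidationError(f"{path}: {'; '.join(parts)}")
    row_order = [row_labels.index(fid) for fid in catalog.ids]
    col_order = [col_labels.index(fid) for fid in catalog.ids]
    return values[np.ix_(row_order, col_order)], catalog.ids


def read_catalog(path: str | Path) -> FactorCatalog:
    """Read a factor catalog from JSON (list of pairs / list of objects /
    id→label mapping) or CSV with columns factor_id,label."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        if isinstance(data, dict):
            pairs = list(data.items())
        else:
            pairs = []
            for item in data:
                if isinstance(item, dict):
                    pairs.append((item["factor_id"], item.get("label", item["factor_id"])))
                else:
                    fid, label = item
                    pairs.append((fid, label))
        return FactorCatalog.from_pairs(pairs)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "factor_id" not in df.columns:
        raise ValidationError(f"{path}: catalog CSV needs a 'factor_id' column")
    labels = df["label"] if "label" in df.columns else df["factor_id"]
    return FactorCatalog.from_pairs(zip(df["factor_id"], labels))


def write_catalog_json(catalog: FactorCatalog, path: str | Path) -> None:
    data = [{"factor_id": fid, "label": label} for fid, label in catalog.factors]
    Path(path).write_text(json.dumps(data, indent=1) + "\n", encoding="utf-8")


def profiles_frame(result: AnalysisResult, precision: int | None = None) -> pd.DataFrame:
    """Profiles table with columns factor_id,label,R,C,prominence,relation,group."""
    rows = []
    for p in result.profiles:
        num = {
            k: (display_round(getattr(p, k), precision) if precision is not None
                else getattr(p, k))
            for k in ("R", "C", "prominence", "relation")
        }
        rows.append({"factor_id": p.factor_id, "label": p.label, **num, "group": p.group})
    return pd.DataFrame(rows)


def write_analysis(
    result: AnalysisResult,
    out_dir: str | Path,
    *,
    precision: int = 2,
    threshold: float | None = None,
    edge_rule: str = "strict",
) -> dict[str, Path]:
    """Write the full artifact set for one analysis.

    Produces A.csv, X.csv, T.csv (display precision), profiles.csv,
    result.json (full precision), network.dot, edges.csv and
    coordinates.csv; deterministic content for a fixed input. ``threshold``
    overrides the mean-of-T threshold for the network only.

    Returns a name → path mapping of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = result.catalog
    theta = result.threshold if threshold is None else float(threshold)
    net = build_network(result.total, result.profiles, theta, edge_rule=edge_rule)

    paths: dict[str, Path] = {}

    def _write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text, encoding="utf-8")
        paths[name] = p

    write_matrix_csv(result.direct.values, catalog, out / "A.csv", precision=precision)
    write_matrix_csv(result.normalized.values, catalog, out / "X.csv", precision=None)
    write_matrix_csv(result.total.values, catalog, out / "T.csv", precision=precision)
    paths.update({n: out / f"{n}.csv" for n in ("A", "X", "T")})

    prof = profiles_frame(result, precision=precision)
    _write("profiles.csv", prof.to_csv(index=False))
    _write(
        "coordinates.csv",
        prof[["factor_id", "prominence", "relation", "group"]].to_csv(index=False),
    )
    _write("network.dot", export_network(net, "dot"))
    _write("edges.csv", export_network(net, "edgelist"))

    payload = {
        "threshold": result.threshold,
        "network_threshold": theta,
        "edge_rule": edge_rule,
        "normalizing_constant": result.normalized.normalizing_constant,
        "profiles": [dataclasses.asdict(p) for p in result.profiles],
        "profiles_display": profiles_frame(result, precision=precision).to_dict(
            orient="records"
        ),
        "threshold_display": display_round(result.threshold, precision + 1),
        "n_edges": net.n_edges,
        "provenance": result.provenance,
    }
    _write("result.json", json.dumps(payload, indent=1) + "\n")
    return paths
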