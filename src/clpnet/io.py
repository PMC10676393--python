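"""Read/write panel data and network artifacts in fixed plain-text formats.

Wide CSV: one row per subject-wave (``id, wave, item_..., covariates``);
long CSV: ``id, wave, item, value``.  Missing cells are empty strings,
never numeric sentinels.  Networks export to an edge-list CSV carrying
both the log-odds and OR scales, and to GraphML with the log-odds weight.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .types import CLPNetwork, GroundTruthSpec, IsingNetwork, PanelDataset

__all__ = [
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "edge_list",
    "export_network",
    "write_ground_truth",
    "read_config",
    "write_config",
]


class PanelFormatError(ValueError):
    """A panel file violates the format contract (bad value, duplicate row)."""


def write_panel(panel: PanelDataset, path, format: str = "wide") -> None:
    path = Path(path)
    vals = panel.values_float()
    n, w, k = vals.shape
    if format == "wide":
        rows = []
        for i in range(n):
            for wi, wave in enumerate(panel.wave_labels):
                rec = {"id": panel.subject_ids[i], "wave": wave}
                for j, item in enumerate(panel.item_labels):
                    v = vals[i, wi, j]
                    rec[item] = "" if np.isnan(v) else int(v)
                for ci, cov in enumerate(panel.covariate_labels):
                    rec[cov] = int(panel.covariates[i, ci])
                rows.append(rec)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "long":
        ids = np.repeat(panel.subject_ids, w * k)
        waves = np.tile(np.repeat(panel.wave_labels, k), n)
        items = np.tile(panel.item_labels, n * w)
        flat = vals.reshape(-1)
        df = pd.DataFrame({"id": ids, "wave": waves, "item": items, "value": flat})
        df["value"] = df["value"].map(lambda v: "" if np.isnan(v) else int(v))
        # covariates ride along in long format as repeated columns
        for ci, cov in enumerate(panel.covariate_labels):
            df[cov] = np.repeat(panel.covariates[:, ci], w * k)
        df.to_csv(path, index=False)
    else:
        raise ValueError("format must be 'wide' or 'long'")


def _coerce_binary(df: pd.DataFrame, columns, context: str):
    for col in columns:
        vals = df[col]
        bad = vals.notna() & ~vals.isin([0, 1, 0.0, 1.0, "0", "1"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelFormatError(
                f"non-binary value {vals.iloc[row]!r} in column {col!r}, "
                f"{context} row {row + 2}"  # +2: header + 1-based
            )


def read_panel(path, format: str = "wide", item_labels=None, covariate_labels=None) -> PanelDataset:
    """Read a panel CSV (wide or long) into a validated :class:`PanelDataset`.

    Wave order is inferred by sorting the wave labels.  Non-binary item
    values and duplicated (id, wave) pairs are hard errors naming the
    offending location.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if format == "long":
        if covariate_labels is None:
            covariate_labels = tuple(
                c for c in df.columns if c not in ("id", "wave", "item", "value")
            )
        dup = df.duplicated(subset=["id", "wave", "item"])
        if dup.any():
            rec = df[dup].iloc[0]
            raise PanelFormatError(
                f"duplicated (id, wave, item) = ({rec['id']}, {rec['wave']}, {rec['item']})"
            )
        _coerce_binary(df, ["value"], f"file {path.name}")
        wide = df.pivot_table(
            index="id", columns=["wave", "item"], values="value", aggfunc="first"
        )
        item_order = item_labels or tuple(dict.fromkeys(df["item"]))
        waves = tuple(sorted(df["wave"].unique()))
        cov_df = df.drop_duplicates("id").set_index("id")[list(covariate_labels)]
        ids = wide.index.to_numpy()
        n, w, k = len(ids), len(waves), len(item_order)
        vals = np.full((n, w, k), np.nan)
        for wi, wave in enumerate(waves):
            for j, item in enumerate(item_order):
                if (wave, item) in wide.columns:
                    vals[:, wi, j] = wide[(wave, item)].to_numpy(dtype=float)
        covariates = cov_df.loc[ids].to_numpy(dtype=float)
    elif format == "wide":
        reserved = ("id", "wave")
        if item_labels is None:
            # items are every non-reserved, non-covariate column; covariates
            # default to known names present in the file
            from .types import DEFAULT_COVARIATES

            covariate_labels = covariate_labels or tuple(
                c for c in DEFAULT_COVARIATES if c in df.columns
            )
            item_labels = tuple(
                c for c in df.columns if c not in reserved and c not in covariate_labels
            )
        covariate_labels = covariate_labels or ()
        dup = df.duplicated(subset=["id", "wave"])
        if dup.any():
            rec = df[dup].iloc[0]
            raise PanelFormatError(f"duplicated (id, wave) = ({rec['id']}, {rec['wave']})")
        _coerce_binary(df, list(item_labels), f"file {path.name}")
        waves = tuple(sorted(df["wave"].unique()))
        ids = df["id"].drop_duplicates().to_numpy()
        id_pos = {v: i for i, v in enumerate(ids)}
        n, w, k = len(ids), len(waves), len(item_labels)
        vals = np.full((n, w, k), np.nan)
        covariates = np.zeros((n, len(covariate_labels)))
        for _, rec in df.iterrows():
            i = id_pos[rec["id"]]
            wi = waves.index(rec["wave"])
            vals[i, wi, :] = [float(rec[c]) if pd.notna(rec[c]) else np.nan for c in item_labels]
            for ci, cov in enumerate(covariate_labels):
                covariates[i, ci] = rec[cov]
        item_order = tuple(item_labels)
    else:
        raise ValueError("format must be 'wide' or 'long'")

    observed = ~np.isnan(vals)
    items = np.where(observed, vals, 0).astype(np.uint8)
    return PanelDataset(
        subject_ids=ids,
        items=items,
        observed=observed,
        covariates=covariates.astype(np.uint8),
        item_labels=tuple(item_order),
        wave_labels=tuple(int(x) for x in waves),
        covariate_labels=tuple(covariate_labels),
    )


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def edge_list(network: CLPNetwork | IsingNetwork) -> pd.DataFrame:
    """Nonzero edges with both weight scales; symmetric edges written once."""
    rows = []
    if isinstance(network, IsingNetwork):
        k = len(network.item_labels)
        for a in range(k):
            for b in range(a + 1, k):
                w = network.weights[a, b]
                if w != 0:
                    rows.append((network.item_labels[a], network.item_labels[b], w))
    else:
        if network.scale != "log_odds":
            raise ValueError("export expects the log-odds scale")
        for i, pl in enumerate(network.predictor_labels):
            for j, ol in enumerate(network.outcome_labels):
                w = network.coef[i, j]
                if w != 0:
                    rows.append((pl, ol, w))
    df = pd.DataFrame(rows, columns=["source", "target", "weight_log_odds"])
    df["weight_or"] = np.exp(df["weight_log_odds"]) if len(df) else pd.Series(dtype=float)
    df["network"] = network.label
    return df


def export_network(network: CLPNetwork | IsingNetwork, basepath) -> tuple[Path, Path]:
    """Write ``<basepath>.csv`` (edge list) and ``<basepath>.graphml``."""
    basepath = Path(basepath)
    csv_path = basepath.with_suffix(".csv")
    gml_path = basepath.with_suffix(".graphml")
    df = edge_list(network)
    df.to_csv(csv_path, index=False)

    g = nx.Graph() if isinstance(network, IsingNetwork) else nx.DiGraph()
    labels = (
        network.item_labels
        if isinstance(network, IsingNetwork)
        else tuple(dict.fromkeys(network.predictor_labels + network.outcome_labels))
    )
    g.add_nodes_from(labels)
    for _, r in df.iterrows():
        g.add_edge(r["source"], r["target"], weight=float(r["weight_log_odds"]))
    nx.write_graphml(g, gml_path)
    return csv_path, gml_path


def write_ground_truth(spec: GroundTruthSpec, path) -> None:
    """Serialize a generative spec to a plain-text key-value (YAML) file."""
    payload = {
        "item_labels": list(spec.item_labels),
        "n_waves": spec.n_waves,
        "wave1_intercepts": spec.wave1_intercepts.tolist(),
        "transition_intercepts": spec.transition_intercepts.tolist(),
        "B": spec.B.tolist(),
        "covariate_labels": list(spec.covariate_labels),
        "covariate_effects": spec.covariate_effects.tolist(),
        "covariate_prevalences": spec.covariate_prevalences.tolist(),
        "attrition_intercept": spec.attrition_intercept,
        "attrition_covariate_coefs": spec.attrition_covariate_coefs.tolist(),
        "attrition_sumscore_coef": spec.attrition_sumscore_coef,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
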