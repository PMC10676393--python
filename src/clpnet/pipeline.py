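"""End-to-end pipeline: simulate/read -> describe -> impute -> networks -> reports.

``run_pipeline`` executes the configured stages in order and writes every
numeric artifact as CSV (plus GraphML for networks) into a run directory,
with a manifest recording versions, seeds and stage timings.  Rerunning
with an identical config and seed reproduces the numeric artifacts
byte-for-byte (the manifest's timings naturally differ).
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clpn import expected_influence, fit_all_clpns
from .comparison import compare_consecutive
from .descriptives import describe_panel
from .io import export_network, read_config, read_panel, write_panel
from .ising import fit_ising
from .missingness import dropout_model, impute_chained, little_mcar_test, panel_to_wide_matrix
from .resampling import bootstrap_edges, casedrop_stability
from .synthetic import apply_attrition, build_ground_truth, simulate_panel

__all__ = ["PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_pipeline(config, out_dir) -> Path:
    """Run the configured stages; returns the run directory.

    ``config`` is a dict or path to a YAML key-value file.  Recognized
    keys: ``seed``; either ``input`` (``{path, format}``) or ``simulate``
    (``{n_subjects, attrition: bool, spec: {...build_ground_truth
    config}}``); ``stages`` (subset of ``describe, missingness, impute,
    clpn, ising, bootstrap, compare``); per-stage option blocks ``clpn``,
    ``ising``, ``bootstrap``.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get(
        "stages", ["describe", "missingness", "impute", "clpn", "compare"]
    ))
    manifest: dict = {
        "clpnet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "stages": stages,
        "timings_s": {},
    }
    log_lines: list[str] = []

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - stage name must reach the user
            raise PipelineError(f"stage {name!r} failed: {e}") from e
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        log_lines.append(f"stage {name}: ok ({manifest['timings_s'][name]} s)")
        return result

    # --- input ------------------------------------------------------------
    def _load():
        if "input" in config:
            inp = config["input"]
            return read_panel(inp["path"], format=inp.get("format", "wide"))
        sim = dict(config.get("simulate", {}))
        spec_cfg = dict(sim.get("spec", {}))
        spec_cfg.setdefault("seed", seed)
        spec = build_ground_truth(spec_cfg)
        panel = simulate_panel(spec, int(sim.get("n_subjects", 1000)), seed=seed)
        if sim.get("attrition", False):
            panel = apply_attrition(panel, spec, seed=seed)
        return panel

    panel = _stage("input", _load)
    write_panel(panel, out / "panel_wide.csv", format="wide")
    manifest["n_subjects"] = int(panel.n_subjects)
    manifest["n_waves"] = int(panel.n_waves)

    if "describe" in stages:
        df = _stage("describe", lambda: describe_panel(panel))
        df.to_csv(out / "descriptives.csv", index=False, float_format=_FLOAT_FMT)

    if "missingness" in stages and not panel.observed.all():
        def _missingness():
            mat, _names = panel_to_wide_matrix(panel)
            mcar = little_mcar_test(mat)
            drop = dropout_model(panel)
            return mcar, drop

        mcar, drop = _stage("missingness", _missingness)
        pd.DataFrame([vars(mcar)]).to_csv(out / "mcar_test.csv", index=False,
                                          float_format=_FLOAT_FMT)
        drop.to_csv(out / "dropout_model.csv", index=False, float_format=_FLOAT_FMT)

    analysis_panel = panel
    if "impute" in stages and not panel.observed.all():
        analysis_panel = _stage(
            "impute", lambda: impute_chained(panel, seed=seed,
                                             n_iterations=int(config.get("impute", {}).get("n_iterations", 20)))
        )
        write_panel(analysis_panel, out / "panel_imputed.csv", format="wide")

    networks = []
    if "clpn" in stages:
        opts = dict(config.get("clpn", {}))
        networks = _stage(
            "clpn", lambda: fit_all_clpns(analysis_panel, seed=seed, **opts)
        )
        cent_rows = []
        for net in networks:
            export_network(net, out / f"clpn_{net.label}")
            ei = expected_influence(net)
            frame = ei.to_frame().reset_index()
            frame.insert(0, "network", net.label)
            cent_rows.append(frame)
        pd.concat(cent_rows, ignore_index=True).to_csv(
            out / "centrality.csv", index=False, float_format=_FLOAT_FMT
        )
        manifest["n_clpn_models"] = len(networks)

    if "ising" in stages:
        opts = dict(config.get("ising", {}))

        def _ising():
            nets = []
            for wi, wave in enumerate(analysis_panel.wave_labels):
                complete = analysis_panel.observed[:, wi, :].all(axis=1)
                m = analysis_panel.items[complete, wi, :]
                nets.append(fit_ising(m, item_labels=analysis_panel.item_labels,
                                      label=f"t{wave}", **opts))
            return nets

        for net in _stage("ising", _ising):
            export_network(net, out / f"ising_{net.label}")

    if "bootstrap" in stages and networks:
        opts = dict(config.get("bootstrap", {}))
        B = int(opts.pop("B", 200))
        wave = int(opts.pop("wave", analysis_panel.wave_labels[0]))

        def _bootstrap():
            dist, ci = bootstrap_edges(analysis_panel, wave, B=B, seed=seed, **opts)
            stab = casedrop_stability(analysis_panel, wave, B=max(B // 4, 10), seed=seed)
            return dist, ci, stab

        dist, ci, stab = _stage("bootstrap", _bootstrap)
        ci.to_csv(out / f"bootstrap_ci_t{wave}.csv", index=False, float_format=_FLOAT_FMT)
        stab.curve().to_csv(out / "stability_curve.csv", index=False, float_format=_FLOAT_FMT)
        manifest["bootstrap"] = {
            "B": B, "completed": int(dist.n_completed),
            "cs_in": stab.cs_in, "cs_out": stab.cs_out,
        }

    if "compare" in stages:
        from .types import NetworkComparison

        comps = _stage("compare", lambda: compare_consecutive(networks))
        pd.DataFrame(
            [c.to_dict() for c in comps],
            columns=list(NetworkComparison.__dataclass_fields__),
        ).to_csv(out / "comparison.csv", index=False, float_format=_FLOAT_FMT)

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
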