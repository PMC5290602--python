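"""Configuration-driven end-to-end runs and report exports.

A single YAML config declares the studies (paths, orientation, tissue —
or a ``simulate`` block that generates them), the analysis parameters for
each stage, and the output directory. :func:`run_pipeline` executes
ingest -> per-study DE -> meta-analysis -> Venn partitioning ->
cooperation analysis, writes every artifact as TSV/JSON, and records a
manifest (inputs, parameters, versions, seed, per-stage row counts and
artifact checksums). Identical config + inputs reproduce identical
checksums. :func:`export_report` derives the plotting-ready tables
(heat-map matrix, forest rows, Venn counts, FC/FC scatters) from the
serialized artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, cooperation as coop_mod, de, io, meta as meta_mod, simulate, venn
from .errors import PipelineError, ValidationError

logger = logging.getLogger(__name__)

DEFAULTS = {
    "de": {"alpha": 0.05, "use_adjusted": False},
    "meta": {"alpha_adj": 0.05, "fc_gate": None, "method": "fixed",
             "convention": "loss_of_function"},
    "venn": {"alpha": 0.05, "use_adjusted": False},
    "cooperation": {"gate": 2.0, "alpha": 0.05, "expected_sign": -1},
}


def load_config(source: str | Path | Mapping) -> dict:
    """Load and validate a pipeline config from YAML (or a mapping)."""
    if isinstance(source, Mapping):
        config = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
    if "studies" not in config and "simulate" not in config:
        raise ValidationError("config needs a 'studies' list or a 'simulate' block")
    for entry in config.get("studies", []):
        for key in ("study_id", "matrix", "samplesheet", "orientation"):
            if key not in entry:
                raise ValidationError(f"study entry missing {key!r}: {entry}")
        for key in ("matrix", "samplesheet", "probe_map"):
            if key in entry and not Path(entry[key]).exists():
                raise ValidationError(
                    f"study {entry['study_id']!r}: file not found: {entry[key]}"
                )
    for pair in config.get("cooperation", {}).get("pairs", []):
        for key in ("x", "y"):
            if key not in pair:
                raise ValidationError(f"cooperation pair missing {key!r}: {pair}")
    return config


def _merged(config: dict, block: str) -> dict:
    out = dict(DEFAULTS[block])
    out.update(config.get(block) or {})
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _ingest(config: dict, outdir: Path) -> tuple[list[io.ExpressionStudy], list[Path]]:
    artifacts: list[Path] = []
    if "simulate" in config:
        sim = dict(config["simulate"])
        seed = int(sim.pop("seed", config.get("seed", 0)))
        paired = bool(sim.pop("paired", False))
        scfg = simulate.SyntheticConfig(**sim)
        datadir = outdir / "data"
        if paired:
            sx, sy, truth = simulate.generate_pair_perturbation(scfg, seed)
            studies = [sx, sy]
        else:
            studies, truth = simulate.generate_multistudy(scfg, seed)
        for s in studies:
            artifacts.extend(io.write_study(s, datadir))
        truth_path = datadir / "truth.tsv"
        truth.to_csv(truth_path, sep="\t")
        artifacts.append(truth_path)
        return studies, artifacts
    studies = []
    for entry in config["studies"]:
        study = io.read_study(
            entry["matrix"],
            entry["samplesheet"],
            study_id=entry["study_id"],
            orientation=entry["orientation"],
            tissue=entry.get("tissue", ""),
            feature_level=entry.get("feature_level", "gene"),
        )
        if "probe_map" in entry:
            pmap = io.ProbeMap.from_tsv(entry["probe_map"])
            study = io.collapse_probes(study, pmap, entry.get("collapse_rule", "max_mean"))
        studies.append(study)
    return studies, artifacts


def run_pipeline(config_source: str | Path | Mapping, outdir: str | Path | None = None) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    config = load_config(config_source)
    outdir = Path(outdir if outdir is not None else config.get("outdir", "demeta_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.get("seed"),
        "parameters": {b: _merged(config, b) for b in DEFAULTS},
        "stages": {},
        "artifacts": {},
    }
    artifacts: list[Path] = []

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    studies, sim_artifacts = stage("ingest")(lambda: _ingest(config, outdir))
    artifacts.extend(sim_artifacts)
    manifest["stages"]["ingest"] = {
        "n_studies": len(studies),
        "genes_per_study": {s.study_id: len(s.genes) for s in studies},
    }

    de_cfg = _merged(config, "de")
    def run_de():
        tables = {}
        for s in studies:
            det = de.empirical_bayes(de.fit_two_group(s))
            path = outdir / f"de_{s.study_id}.tsv"
            de.write_detable(det, path)
            artifacts.append(path)
            tables[s.study_id] = det
        return tables
    detables = stage("de")(run_de)
    manifest["stages"]["de"] = {
        sid: {
            "n_genes": len(d.table),
            "d0": d.d0,
            "s0_sq": d.s0_sq,
            "n_significant": int(de.significant_fraction(
                d, alpha=de_cfg["alpha"], use_adjusted=de_cfg["use_adjusted"]
            ).n_sig),
        }
        for sid, d in detables.items()
    }

    meta_cfg = _merged(config, "meta")
    def run_meta():
        mt = meta_mod.meta_analyze(
            detables.values(), method=meta_cfg["method"], convention=meta_cfg["convention"]
        )
        path = meta_mod.write_metatable(mt, outdir / "meta.tsv")
        artifacts.append(path)
        sig = meta_mod.meta_significant(
            mt, alpha_adj=meta_cfg["alpha_adj"], fc_gate=meta_cfg["fc_gate"]
        )
        sig_path = outdir / "meta_significant.tsv"
        sig.to_csv(sig_path, sep="\t", index_label="gene", float_format="%.10g")
        artifacts.append(sig_path)
        return mt, sig
    metatable, meta_sig = stage("meta")(run_meta)
    manifest["stages"]["meta"] = {
        "n_genes": len(metatable.table),
        "n_significant": len(meta_sig),
        "directions": meta_sig["direction"].value_counts().to_dict(),
    }

    venn_cfg = _merged(config, "venn")
    partition = None
    if len(detables) >= 2:
        def run_venn():
            col = "p_adj" if venn_cfg["use_adjusted"] else "p"
            sig_sets = {}
            for sid, d in detables.items():
                t = d.table
                mask = t[col] < venn_cfg["alpha"]
                label = d.tissue or sid
                sig_sets[label] = dict(zip(t.index[mask], np.sign(t.loc[mask, "log2fc"])))
            part = venn.venn_partition(sig_sets)
            path = venn.write_partition(part, outdir / "venn_partition.tsv")
            artifacts.append(path)
            counts_path = outdir / "venn_counts.json"
            counts_path.write_text(json.dumps(
                {
                    "tissues": list(part.tissues),
                    "pattern_counts": part.pattern_counts(),
                    "category_counts": part.category_counts(),
                    "union_size": len(part),
                },
                indent=2, sort_keys=True,
            ))
            artifacts.append(counts_path)
            return part
        partition = stage("venn")(run_venn)
        manifest["stages"]["venn"] = {
            "union_size": len(partition),
            "category_counts": partition.category_counts(),
        }

    coop_cfg = _merged(config, "cooperation")
    coop_stats = {}
    for pair in config.get("cooperation", {}).get("pairs", []):
        name = f"{pair['x']}_vs_{pair['y']}"
        def run_pair(pair=pair, name=name):
            for key in ("x", "y"):
                if pair[key] not in detables:
                    raise ValidationError(
                        f"cooperation pair references undeclared study {pair[key]!r}"
                    )
            paired = coop_mod.pair_contrasts(detables[pair["x"]], detables[pair["y"]])
            ct = coop_mod.classify_quadrants(
                paired,
                expected_sign=int(pair.get("expected_sign", coop_cfg["expected_sign"])),
                gate=float(pair.get("gate", coop_cfg["gate"])),
                alpha=float(pair.get("alpha", coop_cfg["alpha"])),
            )
            path = coop_mod.write_cooperation(ct, outdir / f"coop_{name}.tsv")
            artifacts.append(path)
            summary = coop_mod.cooperation_summary(ct)
            spath = outdir / f"coop_{name}_summary.json"
            spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
            artifacts.append(spath)
            return summary
        coop_stats[name] = stage(f"cooperation:{name}")(run_pair)
    if coop_stats:
        manifest["stages"]["cooperation"] = coop_stats

    manifest["artifacts"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outdir"] = str(outdir)
    return manifest


def export_report(manifest_or_outdir: Mapping | str | Path, genes: list[str] | None = None) -> dict:
    """Derive plotting-ready report tables from a completed run's artifacts.

    Writes, under ``<outdir>/report``: a gene x tissue log2FC heat-map
    table for the shared-core genes (empty with a header when no gene is
    shared by all tissues), forest-row TSVs for ``genes`` (default: the two
    genes with the smallest combined adjusted p), the Venn count JSON, and
    one FC/FC scatter TSV per cooperation pair.
    """
    if isinstance(manifest_or_outdir, Mapping):
        outdir = Path(manifest_or_outdir["outdir"])
    else:
        outdir = Path(manifest_or_outdir)
        if outdir.name == "manifest.json":
            outdir = outdir.parent
    if not (outdir / "manifest.json").exists():
        raise ValidationError(f"no manifest.json under {outdir}")
    report = outdir / "report"
    report.mkdir(exist_ok=True)
    written: dict[str, str] = {}

    detables = {
        p.stem.removeprefix("de_"): de.read_detable(p) for p in sorted(outdir.glob("de_*.tsv"))
    }
    meta_table = pd.read_csv(outdir / "meta.tsv", sep="\t", index_col="gene")

    # heat-map table: shared-core genes x tissues, harmonized log2FC
    core: list[str] = []
    if (outdir / "venn_partition.tsv").exists():
        part_df = pd.read_csv(
            outdir / "venn_partition.tsv", sep="\t", index_col="gene",
            dtype={"pattern": str},
        )
        n_tissues = len(part_df["pattern"].iloc[0]) if len(part_df) else 0
        core = sorted(part_df.index[part_df["k"] == n_tissues]) if n_tissues else []
    heat = pd.DataFrame(index=pd.Index(core, name="gene"))
    for sid, det in detables.items():
        det = io.harmonize_orientation(det, "loss_of_function")
        label = det.tissue or sid
        heat[label] = det.table["log2fc"].reindex(core)
    heat_path = report / "heatmap_shared_core.tsv"
    heat.to_csv(heat_path, sep="\t", float_format="%.10g")
    written["heatmap"] = str(heat_path)

    # forest rows for selected genes, recomputed from the serialized DE tables
    mt = meta_mod.meta_analyze(detables.values())
    if genes is None:
        genes = list(meta_table.sort_values("p_adj").index[:2])
    for gene in genes:
        rows = meta_mod.forest_rows(mt, gene)
        fpath = report / f"forest_{gene}.tsv"
        rows.to_csv(fpath, sep="\t", index=False, float_format="%.10g")
        written[f"forest_{gene}"] = str(fpath)

    if (outdir / "venn_counts.json").exists():
        target = report / "venn_counts.json"
        target.write_text((outdir / "venn_counts.json").read_text())
        written["venn_counts"] = str(target)

    for coop_path in sorted(outdir.glob("coop_*.tsv")):
        ct = pd.read_csv(coop_path, sep="\t", index_col="gene")
        scatter = ct[["fc_x", "fc_y"]]
        spath = report / f"scatter_{coop_path.stem.removeprefix('coop_')}.tsv"
        scatter.to_csv(spath, sep="\t", float_format="%.10g")
        written[f"scatter_{coop_path.stem}"] = str(spath)
    return written
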