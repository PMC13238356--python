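"""Config-driven orchestration of the full workflow.

Stages (in order): simulate -> qc -> annotate -> deconv -> de -> ccc ->
gradients. Each stage reads the interface files written by its upstream
stages, writes its own under ``outdir/<stage>/`` plus a ``report.json``
with seeds and in/out counts, and can therefore be re-run individually.
A single master seed deterministically derives every per-stage and
per-sample seed, so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as an
from . import deconv as dc
from . import gradients as gr
from . import nichecomm as nc
from . import pseudode as pdm
from . import spatial_core as sc
from . import synthgen as sg
from .synthgen import derive_seed

log = logging.getLogger("dystromap")

STAGES = ("simulate", "qc", "annotate", "deconv", "de", "ccc", "gradients")

#: Background L-R pairs (beyond any planted niche pair) scored in the CCC
#: stage of the demo workflow.
BACKGROUND_LR = [("VIM", "CD44"), ("MIF", "CD44_CD74"), ("APP", "VLDLR"), ("APOE", "VLDLR")]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "dystromap_run"
    # synthetic cohort
    n_rows: int = 12
    n_cols: int = 24
    n_genes: int = 600
    markers_per_type: int = 20
    # annotation
    modules: dict = field(default_factory=lambda: dict(an.DEFAULT_MODULES))
    mixture_iterations: int = 500
    # deconvolution
    deconv_lambda: float = 0.1
    # DE thresholds
    lfc_cutoff: float = 0.5
    de_alpha: float = 0.05
    # CCC parameters
    prop_min: float = 0.6
    fold_min: float = 2.0
    cp_rank: int = 15
    # gradient screen
    gradient_alpha: float = 0.05
    rmse_max: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class MissingArtifactError(FileNotFoundError):
    """A stage was requested before its upstream stage produced outputs."""


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"{path} not found: run the '{stage}' stage first"
        )
    return path


def _write_report(stage_dir: Path, payload: dict) -> None:
    with open(stage_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def _sample_dirs(outdir: Path) -> list:
    root = _need(outdir / "simulate", "simulate")
    meta = pd.read_csv(root / "metadata.csv")
    return [(row["sample"], row["cohort"], root / str(row["sample"])) for _, row in meta.iterrows()]


def _load_reference(outdir: Path):
    root = _need(outdir / "simulate" / "reference", "simulate")
    cm = sc.read_counts(root / "counts.mtx", root / "features.tsv", root / "barcodes.tsv")
    labels = pd.read_csv(root / "cell_labels.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    return cm.dense().T, labels, cm.genes  # cells x genes, labels, genes


def _load_qc(outdir: Path, name: str):
    d = _need(outdir / "qc" / str(name), "qc")
    cm = sc.read_counts(d / "counts.mtx", d / "features.tsv", d / "barcodes.tsv")
    return cm


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    stage_dir = outdir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    seed = derive_seed(cfg.seed, "simulate")
    ref_cfg = sg.ReferenceConfig(
        n_genes=cfg.n_genes, markers_per_type=cfg.markers_per_type, seed=seed
    )
    ref, marker_table = sg.make_reference(ref_cfg)

    ref_dir = stage_dir / "reference"
    ref_dir.mkdir(exist_ok=True)
    ref_cm = sc.CountMatrix(ref.genes, [f"cell{i}" for i in range(len(ref.cell_labels))],
                            np.asarray(ref.counts).T)
    sc.write_counts(ref_cm, ref_dir / "counts.mtx", ref_dir / "features.tsv",
                    ref_dir / "barcodes.tsv")
    pd.Series(ref.cell_labels).to_csv(ref_dir / "cell_labels.tsv", sep="\t",
                                      header=False, index=False)
    marker_table.to_csv(ref_dir / "true_markers.csv", index=False)

    configs = sg.demo_cohort_configs(n_rows=cfg.n_rows, n_cols=cfg.n_cols)
    samples, meta = sg.make_cohort(configs, ref, master_seed=seed,
                                   marker_table=marker_table)
    meta.to_csv(stage_dir / "metadata.csv", index=False)

    lr_rows = []
    for s in samples:
        d = stage_dir / s.name
        d.mkdir(exist_ok=True)
        sc.write_counts(s.counts, d / "counts.mtx", d / "features.tsv", d / "barcodes.tsv")
        sc.write_spot_positions(s.grid, d / "tissue_positions.csv")
        sc.write_region_labels(s.labels, d / "region_labels.tsv")
        s.truth.proportions.to_csv(d / "true_proportions.csv")
        with open(d / "truth.json", "w") as fh:
            json.dump(
                {
                    "zone": s.truth.zone,
                    "de": s.truth.de_table.to_dict("records"),
                    "gradients": s.truth.gradient_table.to_dict("records"),
                    "niche": s.truth.niche_table.to_dict("records"),
                },
                fh,
            )
        for rec in s.truth.niche_table.itertuples():
            lr_rows.append((rec.ligand, rec.receptor))
    lr_rows = sorted(set(lr_rows) | set(BACKGROUND_LR))
    pd.DataFrame(lr_rows, columns=["ligand", "receptor"]).to_csv(
        stage_dir / "lr_pairs.tsv", sep="\t", index=False
    )
    report = {"seed": seed, "n_samples": len(samples),
              "groups": meta["cohort"].value_counts().to_dict()}
    _write_report(stage_dir, report)
    return report


def stage_qc(cfg: PipelineConfig, outdir: Path) -> dict:
    stage_dir = outdir / "qc"
    stage_dir.mkdir(parents=True, exist_ok=True)
    per_sample = {}
    for name, group, d in _sample_dirs(outdir):
        cm = sc.read_counts(d / "counts.mtx", d / "features.tsv", d / "barcodes.tsv")
        labels = sc.read_region_labels(d / "region_labels.tsv")
        filtered, kept, dropped = sc.qc_filter(cm, labels)
        od = stage_dir / str(name)
        od.mkdir(exist_ok=True)
        sc.write_counts(filtered, od / "counts.mtx", od / "features.tsv", od / "barcodes.tsv")
        dropped.to_csv(od / "dropped_spots.csv", index=False)
        per_sample[name] = {
            "spots_in": len(cm.barcodes),
            "spots_kept": len(kept),
            "dropped": dropped.groupby("reason").size().to_dict(),
            "dropped_spots": dropped.to_dict("records"),
            "genes_in": len(cm.genes),
            "genes_kept": len(filtered.genes),
        }
    report = {"samples": per_sample}
    _write_report(stage_dir, report)
    return report


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> dict:
    stage_dir = outdir / "annotate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    annotations, groups = {}, {}
    for name, group, d in _sample_dirs(outdir):
        cm = _load_qc(outdir, name)
        labels = sc.read_region_labels(d / "region_labels.tsv")
        norm = sc.log_normalize(cm)
        seed = derive_seed(cfg.seed, f"annotate:{name}")
        ann, details = an.annotate_sample(
            norm, labels, modules=cfg.modules,
            n_iter=cfg.mixture_iterations, seed=seed,
        )
        rows = []
        for b in norm.barcodes:
            row = {"barcode": b, "label": ann[b]}
            for mod, det in details.items():
                split = det["split"]
                if split is not None:
                    nonfat = [x for x in norm.barcodes if labels.get(x) != "fat"]
                    votes = dict(zip(nonfat, split.vote_fraction))
                    row[f"{mod}_vote"] = votes.get(b, np.nan)
                else:
                    row[f"{mod}_vote"] = np.nan
            rows.append(row)
        pd.DataFrame(rows).to_csv(stage_dir / f"{name}_annotation.tsv", sep="\t", index=False)
        annotations[name] = ann
        groups[name] = group
    comp = an.composition(annotations, groups)
    comp.to_csv(stage_dir / "composition.csv", index=False)
    tests = []
    for lab in an.LABELS:
        try:
            t, p = an.compare_groups(comp[lab].to_numpy(), comp["group"].to_numpy())
            tests.append({"label": lab, "t": t, "p": p})
        except ValueError:
            continue
    pd.DataFrame(tests).to_csv(stage_dir / "group_tests.csv", index=False)
    report = {"n_samples": len(annotations),
              "label_totals": comp[list(an.LABELS)].mean().round(3).to_dict()}
    _write_report(stage_dir, report)
    return report


def stage_deconv(cfg: PipelineConfig, outdir: Path) -> dict:
    stage_dir = outdir / "deconv"
    stage_dir.mkdir(parents=True, exist_ok=True)
    counts, labels, genes = _load_reference(outdir)
    markers = dc.select_markers(counts, labels, genes)
    profiles = dc.build_profiles(counts, labels, genes, markers)
    pd.concat(
        [df.assign(cell_type=t) for t, df in markers.items()], ignore_index=True
    ).to_csv(stage_dir / "markers.csv", index=False)

    per_sample = {}
    for name, group, d in _sample_dirs(outdir):
        cm = _load_qc(outdir, name)
        grid = sc.read_spot_positions(d / "tissue_positions.csv")
        norm = sc.log_normalize(cm)
        adj = sc.hex_neighbors(grid)
        res = dc.deconvolve(norm, profiles, adj, lam=cfg.deconv_lambda)
        res.V.to_csv(stage_dir / f"{name}_proportions.csv")
        res.dominant.to_csv(stage_dir / f"{name}_dominant.tsv", sep="\t", header=False)
        per_sample[name] = {"n_sweeps": res.n_sweeps,
                            "ambiguous": int(res.ambiguous.sum())}
    report = {"samples": per_sample, "n_markers": int(sum(len(v) for v in markers.values()))}
    _write_report(stage_dir, report)
    return report


def stage_de(cfg: PipelineConfig, outdir: Path) -> dict:
    stage_dir = outdir / "de"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sample_inputs, module_inputs = [], []
    for name, group, d in _sample_dirs(outdir):
        cm = _load_qc(outdir, name)
        ann_path = _need(outdir / "annotate" / f"{name}_annotation.tsv", "annotate")
        ann = dict(
            pd.read_csv(ann_path, sep="\t")[["barcode", "label"]].itertuples(
                index=False, name=None
            )
        )
        sample_inputs.append((name, group, cm, None))
        module_inputs.append((name, group, cm, ann))

    results = {}
    for level, inputs in (("sample", sample_inputs), ("module", module_inputs)):
        pb, dropped = pdm.aggregate_pseudobulk(inputs, level=level)
        dropped.to_csv(stage_dir / f"{level}_dropped_profiles.csv", index=False)
        if level == "sample":
            frames = {"all": pb}
        else:
            frames = {}
            for cluster in sorted(pb.meta["cluster"].unique()):
                sel = (pb.meta["cluster"] == cluster).to_numpy()
                sub = pdm.PseudoBulk(pb.genes, pb.Y[sel], pb.meta[sel].reset_index(drop=True))
                if sub.meta.groupby("group").size().min() >= 2 and sub.meta["group"].nunique() == 2:
                    frames[cluster] = sub
        for cluster, sub in frames.items():
            keep = pdm.filter_low_expressed(sub)
            factors = pdm.tmm_factors(sub)
            disp = pdm.estimate_dispersion(sub, factors=factors)
            res = pdm.de_test(sub, factors, disp["per_gene"],
                              lfc_cutoff=cfg.lfc_cutoff, alpha=cfg.de_alpha,
                              genes_mask=keep)
            res["level"] = level
            res["cluster"] = cluster
            res.to_csv(stage_dir / f"de_{level}_{cluster}.csv", index=False)
            results[f"{level}:{cluster}"] = int(res["deg"].sum())
    report = {"n_deg": results}
    _write_report(stage_dir, report)
    return report


def stage_ccc(cfg: PipelineConfig, outdir: Path) -> dict:
    stage_dir = outdir / "ccc"
    stage_dir.mkdir(parents=True, exist_ok=True)
    lr_path = _need(outdir / "simulate" / "lr_pairs.tsv", "simulate")
    pairs = nc.read_lr_table(lr_path)

    all_records = []
    for name, group, d in _sample_dirs(outdir):
        labels = sc.read_region_labels(d / "region_labels.tsv")
        if not any(v == "fat" for v in labels.values()):
            continue
        cm = _load_qc(outdir, name)
        grid = sc.read_spot_positions(d / "tissue_positions.csv")
        norm = sc.log_normalize(cm)
        adj = sc.hex_neighbors(grid.subset(norm.barcodes))
        layers = nc.build_layers(adj, labels)
        dom_path = _need(outdir / "deconv" / f"{name}_dominant.tsv", "deconv")
        dom = dict(pd.read_csv(dom_path, sep="\t", header=None).itertuples(index=False, name=None))
        recs = nc.ccc_scores(norm, layers, dom, pairs, str(name))
        all_records.append(recs)
    if not all_records:
        report = {"n_records": 0, "note": "no fat-bearing samples"}
        _write_report(stage_dir, report)
        return report
    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(stage_dir / "ccc_records.csv", index=False)
    kept = nc.filter_lr(records, prop_min=cfg.prop_min, fold_min=cfg.fold_min)
    kept.to_csv(stage_dir / "ccc_filtered.csv", index=False)

    report = {"n_records": len(records), "n_kept": len(kept)}
    if len(kept):
        tensor = nc.build_tensor(kept)
        bound = min(int(np.prod(tensor.values.shape) // s) for s in tensor.values.shape)
        rank = min(cfg.cp_rank, bound)
        fac = nc.cp_decompose(tensor, rank=rank, seed=derive_seed(cfg.seed, "ccc"))
        for mode, (axis, names) in enumerate(
            zip(fac.factors, [tensor.contexts, tensor.pairs, tensor.senders, tensor.receivers])
        ):
            pd.DataFrame(axis, index=names,
                         columns=[f"factor{r}" for r in range(rank)]).to_csv(
                stage_dir / f"cp_mode{mode}.csv"
            )
        with open(stage_dir / "tensor_axes.json", "w") as fh:
            json.dump({"contexts": tensor.contexts, "pairs": tensor.pairs,
                       "senders": tensor.senders, "receivers": tensor.receivers}, fh)
        report.update({"tensor_shape": list(tensor.values.shape), "cp_rank": rank,
                       "cp_rel_error": fac.rel_error})
    _write_report(stage_dir, report)
    return report


def stage_gradients(cfg: PipelineConfig, outdir: Path) -> dict:
    stage_dir = outdir / "gradients"
    stage_dir.mkdir(parents=True, exist_ok=True)
    per_sample = {}
    for name, group, d in _sample_dirs(outdir):
        labels = sc.read_region_labels(d / "region_labels.tsv")
        if not any(v == "fat" for v in labels.values()):
            continue
        cm = _load_qc(outdir, name)
        grid = sc.read_spot_positions(d / "tissue_positions.csv")
        norm = sc.log_normalize(cm)
        fits = gr.screen_gradients(norm, grid, labels, alpha=cfg.gradient_alpha,
                                   rmse_max=cfg.rmse_max)
        fits.to_csv(stage_dir / f"{name}_gradient_fits.csv", index=False)
        per_sample[name] = {"n_tested": len(fits), "n_selected": int(fits["selected"].sum())}
    report = {"samples": per_sample}
    _write_report(stage_dir, report)
    return report


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "annotate": stage_annotate,
    "deconv": stage_deconv,
    "de": stage_de,
    "ccc": stage_ccc,
    "gradients": stage_gradients,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in canonical order; returns the run report."""
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": cfg.seed, "stages": {}}
    for stage in stages:
        log.info("running stage %s", stage)
        report["stages"][stage] = STAGE_FUNCS[stage](cfg, outdir)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
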