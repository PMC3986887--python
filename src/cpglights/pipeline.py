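"""End-to-end orchestration: simulate -> prepare -> correlate ->
build-models -> scan -> enrich -> annotate, with a digest manifest.

Every stage writes plain-text outputs under the run directory and the
manifest records a SHA-256 digest per file, so reruns with the same
configuration and seed can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, correlation, enrichment, profiles, scanning, synthetic_data
from .errors import PipelineError
from .motif_models import ModelBundle, build_motif_models, write_model_archive

logger = logging.getLogger("cpglights")

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with the study's default thresholds."""

    outdir: Path
    seed: int = 0
    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    alpha: float = 0.01
    model_pvalue: float = 0.0005
    min_coverage: int = 10
    min_class_fraction: float = 0.5
    min_expression: float = 1.0
    min_amplitude: float = 50.0
    min_alignment_n: int = 15
    n_alignment_seqs: int = 400
    normal_only: bool = False
    use_peaks: bool = True
    model_kinds: tuple[str, ...] = ("pwm", "rdm")

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        # the run seed drives the generator
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = synthetic_data.SimulationConfig(**raw.pop("simulation", {}))
        if seed is not None:
            raw["seed"] = seed
        return cls(outdir=Path(outdir), simulation=sim, **raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run(config: RunConfig) -> dict:
    """Run all stages in dependency order and return the manifest.

    A stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest: dict = {"seed": config.seed, "files": {}}

    stages = [
        ("simulate", _stage_simulate),
        ("prepare", _stage_prepare),
        ("correlate", _stage_correlate),
        ("build-models", _stage_models),
        ("scan", _stage_scan),
        ("enrich", _stage_enrich),
        ("annotate", _stage_annotate),
    ]
    for name, fn in stages:
        logger.info("stage %s", name)
        try:
            fn(config, state)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _digest(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    state["manifest"] = manifest
    return state


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict) -> None:
    indir = config.outdir / "inputs"
    state["sim"] = synthetic_data.simulate_all(config.simulation, outdir=indir)


def _stage_prepare(config: RunConfig, state: dict) -> None:
    sim = state["sim"]
    sample_map = sim["sample_map"]
    if config.normal_only:
        sample_map = sample_map[sample_map["normal"]]
    counts = sim["counts"][[s for s in sim["counts"].columns if s in sample_map.index]]
    normalized, size_factors = profiles.rle_normalize(counts)
    class_expr = profiles.average_by_class(normalized, sample_map)
    class_expr = profiles.filter_tss(class_expr, config.min_expression)

    meth = sim["methylation_by_id"]
    meth = meth[meth["sample"].isin(sample_map.index)]
    percent = meth.pivot_table(index="cytosine_id", columns="sample", values="percent_meth")
    coverage = meth.pivot_table(
        index="cytosine_id", columns="sample", values="coverage", aggfunc="sum"
    )
    class_percent = profiles.average_by_class(percent, sample_map)
    class_cov = profiles.sum_by_class(coverage, sample_map)
    n_classes = sample_map["class_id"].nunique()
    class_percent = profiles.filter_cytosines(
        class_percent, class_cov, config.min_coverage, config.min_class_fraction, n_classes
    )
    flags = profiles.differential_flags(class_percent, config.min_amplitude)

    promoters = profiles.define_promoters(sim["clusters"].loc[class_expr.index])
    cyt_pos = sim["truth"].cytosines.loc[class_percent.index, ["chrom", "pos"]]
    pairs = profiles.assign_cytosines_to_promoters(cyt_pos, promoters)

    state.update(
        class_expr=class_expr,
        class_percent=class_percent,
        differential=flags,
        promoters=promoters,
        pairs=pairs,
        sample_map=sample_map,
    )
    prep = config.outdir / "prepared"
    prep.mkdir(exist_ok=True)
    _write(class_expr, prep / "expression_class.tsv")
    _write(class_percent, prep / "methylation_class.tsv")
    _write(size_factors.to_frame("size_factor"), prep / "size_factors.tsv")


def _stage_correlate(config: RunConfig, state: dict) -> None:
    results = correlation.correlate_pairs(
        state["class_percent"], state["class_expr"], state["pairs"]
    )
    calls = correlation.call_traffic_lights(results, state["differential"], config.alpha)
    summary = correlation.summarize_calls(results, state["differential"], alphas=config.alphas)
    state.update(results=results, calls=calls, summary=summary)
    _write(results, config.outdir / "correlations.tsv", index=False)
    _write(calls, config.outdir / "calls.tsv")
    _write(summary, config.outdir / "summary.tsv", index=False)


def _stage_models(config: RunConfig, state: dict) -> None:
    rng = np.random.default_rng([config.seed, 40])
    bundles: dict[str, ModelBundle] = {}
    model_dir = config.outdir / "models"
    model_dir.mkdir(exist_ok=True)
    for spec in config.simulation.motif_set:
        alignment = synthetic_data.simulate_alignment(spec.pcm, config.n_alignment_seqs, rng)
        bundle = build_motif_models(
            alignment,
            target_p=config.model_pvalue,
            min_n=config.min_alignment_n,
            rng=rng,
        )
        if bundle is None:
            logger.warning("%s discarded (fewer than %d sites)", spec.tf_id, config.min_alignment_n)
            continue
        bundles[spec.tf_id] = bundle
        write_model_archive(bundle, model_dir / f"{spec.tf_id}.model.txt")
    state["bundles"] = bundles


def _stage_scan(config: RunConfig, state: dict) -> None:
    sim = state["sim"]
    models = []
    for bundle in state["bundles"].values():
        if "pwm" in config.model_kinds:
            models.append(bundle.pwm)
        if "rdm" in config.model_kinds:
            models.append(bundle.rdm)
    hits = scanning.scan(state["promoters"], sim["sequences"], models)
    if config.use_peaks:
        hits = scanning.restrict_to_peaks(hits, sim["truth"].peaks)
    state["hits"] = hits.reset_index(drop=True)
    _write(state["hits"], config.outdir / "hits.bed", index=False)


def _stage_enrich(config: RunConfig, state: dict) -> None:
    calls = state["calls"]
    truth = state["sim"]["truth"]
    cpgs = truth.cytosines.loc[calls.index, ["chrom", "pos"]].assign(
        negative=(calls["label"] == correlation.LABEL_NEGATIVE),
        positive=(calls["label"] == correlation.LABEL_POSITIVE),
    )
    table = enrichment.enrichment_table(cpgs, state["hits"], sign="negative")
    labels = dict(
        zip(state["sim"]["functions"]["tf"], state["sim"]["functions"]["function"])
    )
    classes = enrichment.compare_function_classes(table, labels)
    pair_classes = {
        (kind, tf): bundle.cpg_pairs
        for tf, bundle in state["bundles"].items()
        for kind in config.model_kinds
    }
    strata, paired = enrichment.positional_enrichment(cpgs, state["hits"], pair_classes)
    state.update(cpgs=cpgs, enrichment=table, function_classes=classes, strata=strata, paired=paired)
    _write(table, config.outdir / "enrichment.tsv", index=False)
    _write(classes, config.outdir / "function_classes.tsv", index=False)
    _write(strata, config.outdir / "positional.tsv", index=False)
    _write(paired, config.outdir / "positional_paired.tsv", index=False)


def _stage_annotate(config: RunConfig, state: dict) -> None:
    calls = state["calls"]
    truth = state["sim"]["truth"]
    coords = truth.cytosines[["chrom", "pos"]]
    sets = {
        "traffic_light": coords.loc[calls.index[calls["label"] == correlation.LABEL_NEGATIVE]],
        "positive": coords.loc[calls.index[calls["label"] == correlation.LABEL_POSITIVE]],
        "insignificant": coords.loc[calls.index[calls["label"] == correlation.LABEL_NONE]],
    }
    promoters = state["promoters"].rename(columns={})[["chrom", "start", "end"]]
    tracks = {"CGI": state["sim"]["cgi"], "promoter": promoters}
    matrix = annotation.colocalize(sets, tracks)
    state["annotation"] = matrix
    _write(matrix, config.outdir / "annotation.tsv")
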