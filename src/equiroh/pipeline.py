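"""End-to-end orchestration of the homozygosity-fertility analysis.

Stages communicate through plain-text files in an output directory and are
recorded in a JSON run manifest (config echo, seed, stage timings, output
paths).  Island detection may run on the divergent-tails cohort while island
validation always runs on the full cohort.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_islands_frame, intersect, read_annotation
from .association import (
    PhenotypeTable,
    compare_group_froh,
    correlations_by_chromosome,
    select_tails,
)
from .genotype_io import qc_filter, read_plink, write_bed, write_plink
from .inbreeding import FrohTable, compute_froh
from .rohi import (
    MarkerPValues,
    ROHIsland,
    call_islands,
    incidence,
    permutation_pvalues,
    validate_islands,
    islands_to_frame,
)
from .roh_scan import ROHParams, detect_roh, read_segments, write_segments
from .synthetic import SimConfig, PlantedIsland, simulate_all
from .genotype_io import SNPMap

STAGES = ("simulate", "qc", "roh", "froh", "associate", "rohi", "validate", "annotate")


class PipelineError(RuntimeError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "equiroh_run",
    "sim": {},  # SimConfig overrides; "islands" is a list of dicts
    "qc": {"min_call_rate": 0.95},
    "roh": {},  # ROHParams overrides
    "tails": {"q": 0.10},
    "nlcor": {"max_segments": 5, "n_perm": 500},
    "rohi": {
        "alpha": 0.01,
        "n_perm": 10_000,
        "min_size_bp": 100_000,
        "max_gap_bp": 100_000,
        "null": "rotate",
        "cohort": "tails",  # or "all"
    },
    "validate": {"t_threshold": 2.0, "min_overlap_frac": 0.5, "min_group_size": 5},
    "annotate": {"file": None, "mode": "any-overlap", "feature_type": "gene"},
    "chromosome_whitelist": None,
}


def merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if key not in cfg:
            raise PipelineError(
                f"unknown config key {key!r}; valid keys: {sorted(cfg)}"
            )
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    sim = dict(cfg["sim"])
    islands = tuple(PlantedIsland(**i) for i in sim.pop("islands", []))
    return replace(SimConfig(seed=cfg["seed"], islands=islands), **sim)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class RunManifest:
    """Accumulates stage records and writes them as JSON."""

    def __init__(self, cfg: dict, out_dir: Path):
        self.out_dir = out_dir
        self.data = {
            "version": __version__,
            "seed": cfg["seed"],
            "config": cfg,
            "stages": [],
        }

    def record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        for p in outputs:
            if not p.exists():
                raise PipelineError(f"stage {stage}: declared output missing: {p}")
        self.data["stages"].append(
            {
                "stage": stage,
                "outputs": [str(p) for p in outputs],
                "digests": {p.name: _digest(p) for p in outputs},
                "seconds": round(elapsed, 3),
            }
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2))
        return path


def _paths(out_dir: Path) -> dict[str, Path]:
    return {
        "map": out_dir / "cohort.map",
        "ped": out_dir / "cohort.ped",
        "phen": out_dir / "phenotypes.tsv",
        "truth": out_dir / "truth.tsv",
        "qc_map": out_dir / "qc.map",
        "qc_ped": out_dir / "qc.ped",
        "qc_report": out_dir / "qc_report.tsv",
        "segments": out_dir / "roh_segments.tsv",
        "froh": out_dir / "froh.tsv",
        "correlations": out_dir / "correlations.tsv",
        "group_froh": out_dir / "group_froh.tsv",
        "tails": out_dir / "tails.tsv",
        "pvalues": out_dir / "marker_pvalues.tsv",
        "islands": out_dir / "islands.tsv",
        "islands_bed": out_dir / "islands.bed",
        "validated": out_dir / "validated_islands.tsv",
        "annotated": out_dir / "annotated_islands.tsv",
    }


def _require(stage: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise PipelineError(f"stage {stage}: missing input {p}")


def _load_qc(paths) -> tuple[SNPMap, "object"]:
    return read_plink(paths["qc_map"], paths["qc_ped"])


def _read_islands(path: Path) -> list[ROHIsland]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        ROHIsland(
            chromosome=r.chromosome,
            start_bp=int(r.start),
            end_bp=int(r.end),
            peak_p=float(r.p_value),
            marker_start=int(getattr(r, "marker_start", -1)),
            marker_stop=int(getattr(r, "marker_stop", -1)),
        )
        for r in df.itertuples()
    ]


def run_stage(name: str, cfg: dict, manifest: RunManifest) -> None:
    """Run one stage, writing its outputs and appending to the manifest."""
    if name not in STAGES:
        raise PipelineError(f"unknown stage {name!r}; stages are: {', '.join(STAGES)}")
    out_dir = manifest.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _paths(out_dir)
    t0 = time.perf_counter()
    outputs: list[Path] = []

    if name == "simulate":
        snpmap, gm, truth, phen = simulate_all(_sim_config(cfg))
        write_plink(snpmap, gm, paths["map"], paths["ped"])
        phen.to_tsv(paths["phen"])
        truth.to_tsv(paths["truth"])
        outputs = [paths["map"], paths["ped"], paths["phen"], paths["truth"]]

    elif name == "qc":
        _require(name, paths["map"], paths["ped"])
        snpmap, gm = read_plink(paths["map"], paths["ped"])
        if cfg["chromosome_whitelist"]:
            keep = snpmap.table["chrom"].isin([str(c) for c in cfg["chromosome_whitelist"]])
            gm_codes = gm.codes[:, keep.to_numpy()]
            snpmap = snpmap.subset(keep.to_numpy())
            gm = type(gm)(gm.individual_ids, gm_codes)
        gm2, map2, report = qc_filter(gm, snpmap, cfg["qc"]["min_call_rate"])
        report.to_tsv(paths["qc_report"])
        write_plink(map2, gm2, paths["qc_map"], paths["qc_ped"])
        outputs = [paths["qc_map"], paths["qc_ped"], paths["qc_report"]]

    elif name == "roh":
        _require(name, paths["qc_map"], paths["qc_ped"])
        snpmap, gm = _load_qc(paths)
        segments = detect_roh(gm, snpmap, ROHParams(**cfg["roh"]))
        write_segments(segments, paths["segments"])
        outputs = [paths["segments"]]

    elif name == "froh":
        _require(name, paths["qc_map"], paths["qc_ped"], paths["segments"])
        snpmap, gm = _load_qc(paths)
        froh = compute_froh(read_segments(paths["segments"]), snpmap, gm.individual_ids)
        froh.to_tsv(paths["froh"])
        outputs = [paths["froh"]]

    elif name == "associate":
        _require(name, paths["froh"], paths["phen"])
        froh = FrohTable.from_tsv(paths["froh"])
        phen = PhenotypeTable.from_tsv(paths["phen"])
        results = correlations_by_chromosome(froh, phen, method="rank")
        pd.DataFrame(
            [
                {
                    "scope": r.scope,
                    "method": r.method,
                    "estimate": r.estimate,
                    "p_value": r.p_value,
                    "n": r.n,
                }
                for r in results
            ]
        ).to_csv(paths["correlations"], sep="\t", index=False)
        tails = select_tails(phen, cfg["tails"]["q"])
        pd.DataFrame(
            {
                "individual_id": tails.high_fert + tails.low_fert,
                "group": ["high_fert"] * len(tails.high_fert)
                + ["low_fert"] * len(tails.low_fert),
            }
        ).to_csv(paths["tails"], sep="\t", index=False)
        compare_group_froh(froh, tails).to_csv(paths["group_froh"], sep="\t", index=False)
        outputs = [paths["correlations"], paths["tails"], paths["group_froh"]]

    elif name == "rohi":
        _require(name, paths["qc_map"], paths["qc_ped"], paths["segments"])
        snpmap, gm = _load_qc(paths)
        segments = read_segments(paths["segments"])
        r = cfg["rohi"]
        if r["cohort"] == "tails":
            _require(name, paths["tails"])
            cohort = pd.read_csv(paths["tails"], sep="\t", dtype=str)["individual_id"].tolist()
        else:
            cohort = list(gm.individual_ids)
        pvals = permutation_pvalues(
            segments, snpmap, cohort, n_perm=r["n_perm"], seed=cfg["seed"], null=r["null"]
        )
        track = incidence(segments, snpmap, cohort)
        pd.DataFrame(
            {
                "marker_id": snpmap.marker_id,
                "chrom": snpmap.chrom,
                "pos": snpmap.pos,
                "incidence": track.observed_count,
                "p": pvals.p,
                "neg_log10_p": pvals.neg_log10_p,
            }
        ).to_csv(paths["pvalues"], sep="\t", index=False)
        islands = call_islands(
            pvals, snpmap, alpha=r["alpha"], min_size_bp=r["min_size_bp"],
            max_gap_bp=r["max_gap_bp"],
        )
        df = pd.DataFrame(
            [
                {
                    "region": f"ROH{i + 1}",
                    "chromosome": isl.chromosome,
                    "start": isl.start_bp,
                    "end": isl.end_bp,
                    "size": isl.size_bp,
                    "p_value": isl.peak_p,
                    "marker_start": isl.marker_start,
                    "marker_stop": isl.marker_stop,
                }
                for i, isl in enumerate(islands)
            ],
            columns=[
                "region", "chromosome", "start", "end", "size",
                "p_value", "marker_start", "marker_stop",
            ],
        )
        df.to_csv(paths["islands"], sep="\t", index=False)
        write_bed(
            [
                (isl.chromosome, isl.start_bp, isl.end_bp, f"ROH{i + 1}")
                for i, isl in enumerate(islands)
            ],
            paths["islands_bed"],
        )
        outputs = [paths["pvalues"], paths["islands"], paths["islands_bed"]]

    elif name == "validate":
        _require(name, paths["islands"], paths["segments"], paths["phen"], paths["qc_ped"])
        snpmap, gm = _load_qc(paths)
        islands = _read_islands(paths["islands"])
        phen = PhenotypeTable.from_tsv(paths["phen"])
        v = cfg["validate"]
        validations = validate_islands(
            islands,
            read_segments(paths["segments"]),
            phen,
            gm.individual_ids,  # whole cohort, never the tails
            t_threshold=v["t_threshold"],
            min_overlap_frac=v["min_overlap_frac"],
            min_group_size=v["min_group_size"],
        )
        islands_to_frame(validations).to_csv(paths["validated"], sep="\t", index=False)
        outputs = [paths["validated"]]

    elif name == "annotate":
        _require(name, paths["validated"])
        ann_file = cfg["annotate"]["file"]
        if not ann_file:
            raise PipelineError("stage annotate: config annotate.file is not set")
        _require(name, Path(ann_file))
        df = pd.read_csv(paths["validated"], sep="\t", dtype={"chromosome": str})
        confirmed = df[df["confirmed"]]
        islands = [
            ROHIsland(r.chromosome, int(r.start), int(r.end), float(r.p_value), -1, -1)
            for r in confirmed.itertuples()
        ]
        genes = read_annotation(ann_file, cfg["annotate"]["feature_type"])
        lists = intersect(islands, genes, mode=cfg["annotate"]["mode"])
        annotate_islands_frame(confirmed.reset_index(drop=True), lists).to_csv(
            paths["annotated"], sep="\t", index=False
        )
        outputs = [paths["annotated"]]

    manifest.record(name, outputs, time.perf_counter() - t0)


def run_all(user_config: dict | None = None, skip_annotate_if_unset: bool = True) -> RunManifest:
    """Run every stage in order on a synthetic (or ingested) cohort."""
    cfg = merge_config(user_config)
    out_dir = Path(cfg["out_dir"])
    manifest = RunManifest(cfg, out_dir)
    for stage in STAGES:
        if stage == "annotate" and not cfg["annotate"]["file"] and skip_annotate_if_unset:
            continue
        try:
            run_stage(stage, cfg, manifest)
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
    manifest.write()
    return manifest
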