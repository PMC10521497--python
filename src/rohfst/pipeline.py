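"""End-to-end orchestration: QC -> PCA -> ROH -> F_ROH -> hotspots -> F_ST.

``run_pipeline`` takes a :class:`PipelineConfig` that either points at a
PED/MAP pair or embeds a :class:`~rohfst.simulate.SimConfig`, runs the
enabled stages in order, and writes every result as a plain TSV (plus BED
for intervals) into the output directory, together with a JSON manifest
recording every parameter and seed so any number in any output can be
reproduced.  Each stage consumes the in-memory dataset but all inter-stage
contracts are also serialised, so stages can be re-run standalone on the
previous stage's files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fst as fst_mod
from . import hotspots as hot_mod
from . import pca as pca_mod
from . import qc as qc_mod
from . import roh as roh_mod
from .io import (
    GenotypeDataset,
    read_ped_map,
    write_bed_intervals,
    write_segments_tsv,
)
from .simulate import SimConfig, inject_noise, simulate_populations

logger = logging.getLogger("rohfst")


@dataclass
class PipelineConfig:
    # input: either a PED/MAP pair or a simulation config
    ped_path: str | None = None
    map_path: str | None = None
    sim: SimConfig | None = None
    out_dir: str = "rohfst_out"
    # stage parameters
    marker_call_rate: float = 0.99
    indiv_call_rate: float = 0.90
    pca_components: int = 2
    pca_scale: bool = False
    roh_params: roh_mod.ROHParams = field(default_factory=roh_mod.ROHParams)
    l_auto_bp: int = roh_mod.GOAT_L_AUTO_BP
    hotspot_threshold: float = 0.40
    hotspot_min_snps: int = 20
    fst_pairs: list[tuple[str, str]] | None = None
    top_k: int = 10
    flank_bp: int = 500_000
    # stage toggles
    run_qc: bool = True
    run_pca: bool = True
    run_roh: bool = True
    run_hotspots: bool = True
    run_fst: bool = True

    def validate(self) -> None:
        have_files = self.ped_path is not None and self.map_path is not None
        if have_files == (self.sim is not None):
            raise ValueError(
                "config needs exactly one input: a PED/MAP pair or a "
                "simulation config"
            )


def _manifest(cfg: PipelineConfig, outputs: list[str]) -> dict:
    d = {
        "ped_path": cfg.ped_path,
        "map_path": cfg.map_path,
        "out_dir": cfg.out_dir,
        "marker_call_rate": cfg.marker_call_rate,
        "indiv_call_rate": cfg.indiv_call_rate,
        "pca_components": cfg.pca_components,
        "pca_scale": cfg.pca_scale,
        "roh_params": asdict(cfg.roh_params),
        "l_auto_bp": cfg.l_auto_bp,
        "hotspot_threshold": cfg.hotspot_threshold,
        "hotspot_min_snps": cfg.hotspot_min_snps,
        "fst_pairs": cfg.fst_pairs,
        "top_k": cfg.top_k,
        "flank_bp": cfg.flank_bp,
        "stages": {
            "qc": cfg.run_qc,
            "pca": cfg.run_pca,
            "roh": cfg.run_roh,
            "hotspots": cfg.run_hotspots,
            "fst": cfg.run_fst,
        },
        "outputs": outputs,
    }
    if cfg.sim is not None:
        sim = asdict(cfg.sim)
        sim["n_per_pop"] = list(cfg.sim.n_per_pop)
        d["simulation"] = sim
    return d


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the enabled stages; return a name -> path map of written files."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, fname: str, writer) -> None:
        path = out / fname
        writer(path)
        written[name] = path

    stage = "input"
    try:
        if cfg.sim is not None:
            ds, _truth = simulate_populations(cfg.sim)
            rng = np.random.default_rng((cfg.sim.seed or 0) + 1)
            inject_noise(ds, cfg.sim.missing_rate, cfg.sim.het_error_rate, rng)
        else:
            ds = read_ped_map(cfg.ped_path, cfg.map_path)
        logger.info(
            "input: %d individuals x %d markers", ds.n_individuals, ds.n_markers
        )

        if cfg.run_qc:
            stage = "qc"
            ds, report = qc_mod.filter_dataset(
                ds, cfg.marker_call_rate, cfg.indiv_call_rate
            )
            logger.info("qc: %s", report.summary().replace("\n", "; "))
            mk, ind = report.to_frames()

            def write_qc(path: Path) -> None:
                with open(path, "w") as fh:
                    fh.write("# " + report.summary().replace("\n", "\n# ") + "\n")
                    fh.write("table\tid\treason\n")
                    for _, r in mk.iterrows():
                        fh.write(f"marker\t{r.snp_id}\t{r.reason}\n")
                    for _, r in ind.iterrows():
                        fh.write(f"individual\t{r.individual_id}\t{r.reason}\n")

            emit("qc_report", "qc_report.tsv", write_qc)
        else:
            ds = ds.sorted_by_map()

        if cfg.run_pca:
            stage = "pca"
            ncomp = min(cfg.pca_components, ds.n_individuals, ds.n_markers)
            res = pca_mod.run_pca(ds, ncomp, scale=cfg.pca_scale)
            scores = pd.DataFrame(
                res.scores, columns=[f"PC{k + 1}" for k in range(ncomp)]
            )
            scores.insert(0, "population", ds.individuals["population"])
            scores.insert(0, "individual_id", ds.individuals["individual_id"])
            emit(
                "pca_scores",
                "pca_scores.tsv",
                lambda p: scores.to_csv(p, sep="\t", index=False),
            )
            vf = pd.DataFrame(
                {
                    "component": [f"PC{k + 1}" for k in range(ncomp)],
                    "variance_fraction": res.variance_fraction,
                }
            )
            emit(
                "pca_variance",
                "pca_variance.tsv",
                lambda p: vf.to_csv(p, sep="\t", index=False),
            )

        segments = None
        if cfg.run_roh:
            stage = "roh"
            segments = roh_mod.detect_roh(ds, cfg.roh_params)
            logger.info("roh: %d segments", len(segments))
            emit(
                "segments",
                "roh_segments.tsv",
                lambda p: write_segments_tsv(segments, p),
            )
            summary = roh_mod.breed_summary_frame(
                roh_mod.summarize_by_breed(segments, ds)
            )
            emit(
                "breed_summary",
                "roh_breed_summary.tsv",
                lambda p: summary.to_csv(p, sep="\t", index=False),
            )
            stage = "froh"
            froh = roh_mod.froh_table(segments, ds, cfg.l_auto_bp)
            emit(
                "froh",
                "froh_individuals.tsv",
                lambda p: froh.to_csv(p, sep="\t", index=False),
            )

        if cfg.run_hotspots and segments is not None:
            stage = "hotspots"
            tracks = []
            regions = []
            for pop in ds.populations():
                track = hot_mod.incidence(segments, ds, pop)
                tab = hot_mod.manhattan_table(track, ds)
                tab.insert(0, "population", pop)
                tracks.append(tab)
                regions.extend(
                    hot_mod.call_hotspots(
                        track,
                        ds,
                        threshold=cfg.hotspot_threshold,
                        min_snps=cfg.hotspot_min_snps,
                    )
                )
            inc = pd.concat(tracks, ignore_index=True)
            emit(
                "incidence",
                "roh_incidence.tsv",
                lambda p: inc.to_csv(p, sep="\t", index=False),
            )
            hs = hot_mod.hotspot_frame(regions)
            emit(
                "hotspots",
                "roh_hotspots.tsv",
                lambda p: hs.to_csv(p, sep="\t", index=False),
            )
            emit(
                "hotspots_bed",
                "roh_hotspots.bed",
                lambda p: write_bed_intervals(
                    [
                        (r.chromosome, r.start_bp, r.end_bp, r.population)
                        for r in regions
                    ],
                    p,
                ),
            )

        if cfg.run_fst:
            stage = "fst"
            pops = ds.populations()
            pairs = cfg.fst_pairs or [
                (pops[i], pops[j])
                for i in range(len(pops))
                for j in range(i + 1, len(pops))
            ]
            per_snp = []
            top_rows = []
            mat = pd.DataFrame(float("nan"), index=pops, columns=pops)
            for a, b in pairs:
                pf = fst_mod.pairwise_fst(ds, a, b)
                mat.loc[a, b] = mat.loc[b, a] = pf.mean_theta
                rec = pf.records.copy()
                rec.insert(0, "pair", f"{a}~{b}")
                per_snp.append(rec)
                tw = fst_mod.top_snps(pf, ds, cfg.top_k, cfg.flank_bp)
                tw.insert(0, "pair", f"{a}~{b}")
                top_rows.append(tw)
            emit(
                "fst_matrix",
                "fst_matrix.tsv",
                lambda p: mat.to_csv(p, sep="\t"),
            )
            allrec = pd.concat(per_snp, ignore_index=True)
            emit(
                "fst_per_snp",
                "fst_per_snp.tsv",
                lambda p: allrec.to_csv(p, sep="\t", index=False),
            )
            alltop = pd.concat(top_rows, ignore_index=True)
            emit(
                "fst_top_windows",
                "fst_top_windows.tsv",
                lambda p: alltop.to_csv(p, sep="\t", index=False),
            )
    except Exception:
        logger.error("pipeline failed in stage %r; partial outputs kept", stage)
        raise

    manifest = _manifest(cfg, [str(p) for p in written.values()])
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    written["manifest"] = mpath
    return written
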