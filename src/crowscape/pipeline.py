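"""Orchestration: simulate -> ingest -> stats -> haploscan -> decompose.

One YAML config drives the whole run; every stage writes TSV outputs into
the run directory and records itself in a manifest with content hashes of
its inputs and outputs. A re-run with the same config skips stages whose
input hash is unchanged and whose outputs are still present, so partial
reruns reproduce identical downstream files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, haplostats, landscape, sitestats, variantio
from .simdata import SimConfig, default_scenario, simulate, write_sim_output

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

ALL_STAGES = ("simulate", "ingest", "stats", "haploscan", "decompose")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    window_size: int = 50_000
    stages: tuple[str, ...] = ALL_STAGES
    # either a simulation scenario ...
    simulate: dict = field(default_factory=dict)
    # ... or explicit input paths {vcf, mask, popmap}
    paths: dict = field(default_factory=dict)
    focal_pairs: list[tuple[str, str]] = field(default_factory=list)
    control_pairs: list[tuple[str, str]] = field(default_factory=list)
    percentile: float = 99.0
    alpha_low: float = 0.005
    alpha_high: float = 0.995
    n_perm: int = 1000
    haploscan_pops: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        comparisons = raw.pop("comparisons", {})
        return cls(
            outdir=Path(raw.pop("outdir")),
            seed=int(raw.pop("seed", 0)),
            window_size=int(raw.pop("window_size", 50_000)),
            stages=tuple(raw.pop("stages", ALL_STAGES)),
            simulate=raw.pop("simulate", {}) or {},
            paths=raw.pop("paths", {}) or {},
            focal_pairs=[tuple(p) for p in comparisons.get("focal", [])],
            control_pairs=[tuple(p) for p in comparisons.get("controls", [])],
            percentile=float(raw.pop("percentile", 99.0)),
            alpha_low=float(raw.pop("alpha_low", 0.005)),
            alpha_high=float(raw.pop("alpha_high", 0.995)),
            n_perm=int(raw.pop("n_perm", 1000)),
            haploscan_pops=list(raw.pop("haploscan_pops", [])),
        )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"version": __version__, "stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def up_to_date(self, stage: str, input_hash: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        return (rec is not None and rec["input_hash"] == input_hash
                and all(Path(p).exists() for p in rec["outputs"])
                and set(rec["outputs"]) == {str(p) for p in outputs})

    def record(self, stage: str, input_hash: str, outputs: list[Path],
               seconds: float, seed: int | None) -> None:
        self.data["stages"][stage] = {
            "input_hash": input_hash,
            "outputs": [str(p) for p in outputs],
            "output_hashes": {str(p): _hash_file(Path(p)) for p in outputs},
            "seconds": round(seconds, 3),
            "seed": seed,
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _sim_config(cfg: RunConfig) -> SimConfig:
    opts = dict(cfg.simulate)
    opts.pop("scenario", None)
    return default_scenario(seed=cfg.seed, **opts)


def run_all(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Any stage failure aborts with the stage name in the exception message.
    Returns the manifest dictionary.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump({
            "outdir": str(cfg.outdir), "seed": cfg.seed,
            "window_size": cfg.window_size, "stages": list(cfg.stages),
            "simulate": cfg.simulate, "paths": {k: str(v) for k, v in cfg.paths.items()},
            "comparisons": {"focal": [list(p) for p in cfg.focal_pairs],
                            "controls": [list(p) for p in cfg.control_pairs]},
            "percentile": cfg.percentile, "n_perm": cfg.n_perm,
            "alpha_low": cfg.alpha_low, "alpha_high": cfg.alpha_high,
            "haploscan_pops": cfg.haploscan_pops,
        }, fh, sort_keys=False)
    manifest = _Manifest(out / "manifest.json")

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        try:
            _run_stage(stage, cfg, out, manifest, state)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    return manifest.data


def _run_stage(stage: str, cfg: RunConfig, out: Path, manifest: _Manifest,
               state: dict) -> None:
    t0 = time.monotonic()
    if stage == "simulate":
        sim_cfg = _sim_config(cfg)
        input_hash = _hash_obj(sim_cfg.to_dict())
        simdir = out / "sim"
        outputs = [simdir / n for n in
                   ("sim.vcf", "mask.bed", "popmap.tsv", "covariates.tsv",
                    "truth_windows.tsv")]
        state["paths"] = {"vcf": simdir / "sim.vcf", "mask": simdir / "mask.bed",
                          "popmap": simdir / "popmap.tsv",
                          "covariates": simdir / "covariates.tsv"}
        if manifest.up_to_date(stage, input_hash, outputs):
            logger.info("stage simulate up to date")
            return
        paths = write_sim_output(simulate(sim_cfg), simdir)
        manifest.record(stage, input_hash, outputs, time.monotonic() - t0, cfg.seed)
        return

    paths = state.get("paths") or {k: Path(v) for k, v in cfg.paths.items()}
    state["paths"] = paths

    if stage == "ingest":
        popmap = variantio.read_popmap(paths["popmap"])
        vm = variantio.load_variants(paths["vcf"], paths.get("mask"), popmap)
        windex = variantio.assign_windows(vm, cfg.window_size, paths.get("mask"))
        state["vm"], state["windex"], state["popmap"] = vm, windex, popmap
        win_path = out / "windows.tsv"
        windex.windows.to_csv(win_path, sep="\t", index=False)
        input_hash = _hash_obj([_hash_file(Path(paths["vcf"])), cfg.window_size])
        manifest.record(stage, input_hash, [win_path], time.monotonic() - t0, None)
        return

    if "vm" not in state:
        popmap = variantio.read_popmap(paths["popmap"])
        state["popmap"] = popmap
        state["vm"] = variantio.load_variants(paths["vcf"], paths.get("mask"), popmap)
        state["windex"] = variantio.assign_windows(state["vm"], cfg.window_size,
                                                   paths.get("mask"))
    vm, windex, popmap = state["vm"], state["windex"], state["popmap"]
    pairs = list(cfg.focal_pairs) + list(cfg.control_pairs)

    if stage == "stats":
        frames = []
        for pa, pb in pairs:
            frames.append(sitestats.pair_window_fst(vm, pa, pb, windex)
                          .to_frame(windex.windows))
            frames.append(sitestats.dxy(vm, pa, pb, windex).to_frame(windex.windows))
        for popl in popmap.populations:
            div = sitestats.diversity_stats(vm, popl, windex)
            for statn in ("pi", "theta_w", "tajimas_d", "fay_wu_h", "fu_li_d"):
                tr = sitestats.WindowTrack(statn, popl, div[statn].to_numpy(),
                                           div["n_segregating"].to_numpy())
                frames.append(tr.to_frame(windex.windows))
        tracks = pd.concat(frames, ignore_index=True)
        path = out / "window_tracks.tsv"
        tracks.to_csv(path, sep="\t", index=False)
        state["tracks"] = tracks
        input_hash = _hash_obj([_hash_file(Path(paths["vcf"])), cfg.window_size,
                                sorted(map(list, pairs))])
        manifest.record(stage, input_hash, [path], time.monotonic() - t0, None)
        return

    if stage == "haploscan":
        haps, scaf, pos = variantio.load_haplotypes(paths["vcf"], popmap,
                                                    paths.get("mask"))
        pops = cfg.haploscan_pops or sorted({p for pair in cfg.focal_pairs for p in pair})
        frames = []
        for popl in pops:
            hs = haplostats.HaplotypeSet(haps[popl], scaf, pos)
            for statn, fn in (("ihs", haplostats.ihh_and_ihs), ("nsl", haplostats.nsl)):
                df = fn(hs)
                df.insert(0, "population", popl)
                df.insert(1, "statistic", statn)
                df["outlier"] = haplostats.snp_outliers(
                    df["standardized"].to_numpy(), cfg.alpha_low, cfg.alpha_high)
                frames.append(df)
        res = pd.concat(frames, ignore_index=True)
        path = out / "haplotype_outliers.tsv"
        res.to_csv(path, sep="\t", index=False)
        input_hash = _hash_obj([_hash_file(Path(paths["vcf"])), sorted(pops),
                                cfg.alpha_low, cfg.alpha_high])
        manifest.record(stage, input_hash, [path], time.monotonic() - t0, None)
        return

    if stage == "decompose":
        if not cfg.focal_pairs or not cfg.control_pairs:
            raise ValueError("decompose needs focal and control pairs")
        fst = {}
        for pa, pb in pairs:
            fst[f"{pa}~{pb}"] = sitestats.pair_window_fst(vm, pa, pb, windex).values
        ctrl_z = [landscape.zscore_fst(fst[f"{pa}~{pb}"]) for pa, pb in cfg.control_pairs]
        outputs = []
        all_peaks = []
        for pa, pb in cfg.focal_pairs:
            label = f"{pa}~{pb}"
            z = landscape.zscore_fst(fst[label])
            delta = landscape.delta_fst(z, ctrl_z)
            z_flags = landscape.call_outlier_windows(z, cfg.percentile)
            d_flags = landscape.call_outlier_windows(delta, cfg.percentile)
            peaks = landscape.classify_peaks(z_flags, d_flags, windex.windows,
                                             fst_prime=z, delta=delta)
            pf = landscape.peaks_to_frame(peaks)
            pf.insert(0, "comparison", label)
            all_peaks.append(pf)
            obs, p, _ = landscape.clustering_test(z_flags, windex.windows,
                                                  cfg.n_perm, cfg.seed)
            moran, _ = landscape.morans_i(z, windex.windows)
            (out / f"decompose_{label}.json").write_text(json.dumps({
                "comparison": label,
                "n_outlier_windows": int(z_flags.sum()),
                "n_delta_outlier_windows": int(d_flags.sum()),
                "mean_run_length": obs, "clustering_p": p, "morans_i": moran,
            }, indent=2))
            outputs.append(out / f"decompose_{label}.json")
        peaks_df = pd.concat(all_peaks, ignore_index=True)
        peaks_path = out / "peaks.tsv"
        peaks_df.to_csv(peaks_path, sep="\t", index=False)
        bed_path = out / "peaks.bed"
        with open(bed_path, "w") as fh:
            for _, r in peaks_df.iterrows():
                fh.write(f"{r['scaffold']}\t{r['start']}\t{r['end']}\t{r['class']}\n")
        outputs.extend([peaks_path, bed_path])
        input_hash = _hash_obj([_hash_file(Path(paths["vcf"])), cfg.percentile,
                                cfg.n_perm, cfg.seed, sorted(map(list, pairs))])
        manifest.record(stage, input_hash, outputs, time.monotonic() - t0, cfg.seed)
        return

    raise ValueError(f"unknown stage {stage!r}")
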