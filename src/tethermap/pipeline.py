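"""End-to-end demo pipeline driven by one YAML config.

Stages: simulate -> fragments -> tracks -> aggregate / peaks / contacts /
solubility.  Every run writes a manifest (command line, config snapshot,
output checksums, version, timestamp) so outputs are attributable and
deterministic reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import yaml

from . import __version__, aggregate, contacts, fragments, peaks, simulate, solubility, tracks

KNOWN_STAGES = ("simulate", "tracks", "aggregate", "peaks", "contacts", "solubility")


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    for field in ("seed", "outdir", "stages"):
        if field not in cfg:
            raise ConfigError(f"config missing required field: {field}")
    unknown = [s for s in cfg["stages"] if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stage name(s): {unknown}; known: {list(KNOWN_STAGES)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_path: str | Path) -> Path:
    """Execute the stages named in the config; returns the output directory."""
    cfg = load_config(config_path)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])

    sim_over = dict(cfg.get("simulate", {}))
    sim_cfg = simulate.default_config(seed=seed, **sim_over)
    genome, truth, cs, spike_cs = simulate.make_genome(sim_cfg)
    prim, spk = simulate.simulate_fragments(sim_cfg, truth, cs, spike_cs, time_index=0)

    if "simulate" in stages:
        simulate.write_fasta(genome, outdir / "genome.fa")
        cs.to_file(outdir / "genome.chrom.sizes")
        spike_cs.to_file(outdir / "spike.chrom.sizes")
        truth.to_bed(outdir / "truth_sites.bed")
        prim.to_bed(outdir / "fragments.bed")
        truth.contact_pairs().to_csv(outdir / "truth_contacts.bedpe",
                                     sep="\t", header=False, index=False)

    tracks_cfg = cfg.get("tracks", {})
    size_max = tracks_cfg.get("max_len", 120)
    fs_tf = fragments.size_select(prim, max_len=size_max)
    end_t = tracks.end_density_track(fs_tf, cs)
    cov_t = tracks.coverage_track(fs_tf, cs)
    norm = tracks_cfg.get("norm", "spikein")
    if norm == "spikein":
        end_n = tracks.normalize_spikein(end_t, len(spk))
        cov_n = tracks.normalize_spikein(cov_t, len(spk))
    elif norm == "standard":
        end_n = tracks.normalize_standard(end_t, 2 * len(prim))
        cov_n = tracks.normalize_standard(cov_t, 2 * len(prim))
    else:
        end_n, cov_n = end_t, cov_t
    if "tracks" in stages:
        tracks.write_bedgraph(end_n, outdir / "ends.bedgraph")
        tracks.write_bedgraph(cov_n, outdir / "coverage.bedgraph")

    if "aggregate" in stages:
        agg_cfg = cfg.get("aggregate", {})
        flank = int(agg_cfg.get("flank", 1000))
        m = aggregate.site_matrix(end_n, truth.site_tuples("direct"), flank=flank)
        prof = aggregate.mean_profile(m)
        prof.to_tsv(outdir / "end_density_profile.tsv")
        scores = aggregate.occupancy_scores(m, scheme="span-mean",
                                            span=(-flank, flank))
        ordered, _ = aggregate.order_rows(m, scores)
        ordered.to_tsv(outdir / "site_matrix_ordered.tsv")

    called = None
    if "peaks" in stages or "contacts" in stages:
        pk_cfg = cfg.get("peaks", {})
        called = peaks.call_peaks(cov_n,
                                  percentile=pk_cfg.get("percentile", 99.5),
                                  interpeak=pk_cfg.get("interpeak", 100),
                                  min_width=pk_cfg.get("min_width", 50),
                                  max_width=pk_cfg.get("max_width", 1000))
    if "peaks" in stages:
        peaks.peaks_to_bed(called, outdir / "peaks.bed")
        with open(outdir / "peaks.params.json", "w") as fh:
            json.dump({"percentile": cfg.get("peaks", {}).get("percentile", 99.5),
                       "interpeak": 100, "min_width": 50, "max_width": 1000,
                       "nonzero_only": True}, fh, indent=2)

    if "contacts" in stages:
        native = truth.of_class("direct")[["chrom", "start", "end"]]
        classified = contacts.classify_sites(called, native)
        pairs = contacts.anchor_intersect(truth.contact_pairs(), classified)
        pairs.to_csv(outdir / "contacts_annotated.tsv", sep="\t", index=False)

    if "solubility" in stages:
        soluble, total = simulate.simulate_fractions(sim_cfg, prim)
        cov_sol = tracks.normalize_spikein(tracks.coverage_track(soluble, cs), len(spk))
        cov_tot = tracks.normalize_spikein(tracks.coverage_track(total, cs), len(spk))
        ratio = solubility.insoluble_log_ratio(cov_tot, cov_sol, pseudocount=1e-4)
        cen = truth.of_class("centromere")
        prof = solubility.median_midpoint_profile(
            ratio, list(zip(cen["chrom"], cen["center"])), flank=500)
        prof.to_tsv(outdir / "insoluble_centromere_profile.tsv")

    manifest = {
        "command": " ".join(sys.argv),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": cfg,
        "sim_config": dataclasses.asdict(sim_cfg),
        "outputs": {},
    }
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
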