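"""Configuration-driven orchestration of the full analysis.

A single YAML (or dict) config drives: simulate-or-ingest -> filter ->
polarized frequencies -> genome-wide and per-contig D -> windowed f_dM
with outlier calling -> f3 -> windowed diversity statistics -> joint SFS
(-> optional pulse-direction test).  Outputs are plain TSV/JSON plus a
manifest (config echo, seeds, version); a rerun with the same config
reproduces the bundle byte for byte (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coalsim, demography, genotypes, introgression, popgen

__all__ = ["DEFAULTS", "validate_config", "run"]

DEFAULTS: dict = {
    "preset": "study_pulse",
    "phi": 0.1,
    "vcf": None,
    "popmap": None,
    "sampling": {"HS": 4, "TP_E": 4, "TP_M": 4, "TP_W": 4, "J": 2},
    "n_loci": 190,
    "locus_length": 1000,
    "n_contigs": 19,
    "degrade": {"missing_rate": 0.0, "qual": 60.0},
    "filters": {"max_missing": 0.20, "min_qual": 30.0, "min_maf": 0.05},
    "roles": {"P1": "TP_W", "P2": "TP_E", "P3": "HS", "O": "J"},
    "sfs_pair": None,  # default: (P2, P3) populations
    "window_width": 10_000,
    "min_sites_per_window": 5,
    "block_size_snps": 1000,
    "f3_block_size": 500,
    "quantile": 0.95,
    "ti_points": 16,
    "direction": {"enabled": False, "pulse_time": 1000.0, "base": None},
    "seed": 1,
    "outdir": "introflow_out",
    "stages": ["simulate", "filter", "freqs", "dstat", "fdm", "f3",
               "windows", "sfs"],
}

_VALID_STAGES = {"simulate", "filter", "freqs", "dstat", "fdm", "f3",
                 "windows", "sfs", "direction"}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def validate_config(source) -> dict:
    """Normalize a config path/dict: fill defaults, reject unknown keys,
    range-check values.  Raises :class:`ConfigError` listing every
    violation with its key path."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    errors = []
    unknown = set(raw) - set(DEFAULTS)
    for k in sorted(unknown):
        errors.append(f"unknown key: {k}")
    cfg = {}
    for key, default in DEFAULTS.items():
        val = raw.get(key, default)
        if isinstance(default, dict) and isinstance(val, dict) and default:
            sub_unknown = set(val) - set(default)
            for k in sorted(sub_unknown):
                errors.append(f"unknown key: {key}.{k}")
            val = {**default, **{k: v for k, v in val.items() if k in default}}
        cfg[key] = val
    if not 0.0 < cfg["quantile"] < 1.0:
        errors.append("quantile: must be in (0, 1)")
    if not 0.0 <= cfg["phi"] <= 1.0:
        errors.append("phi: must be in [0, 1]")
    if not isinstance(cfg["seed"], int):
        errors.append("seed: must be an integer")
    if cfg["ti_points"] < 2:
        errors.append("ti_points: must be >= 2")
    if cfg["window_width"] <= 0:
        errors.append("window_width: must be positive")
    f = cfg["filters"]
    if not 0 < f["max_missing"] <= 1:
        errors.append("filters.max_missing: must be in (0, 1]")
    if not 0 <= f["min_maf"] < 0.5:
        errors.append("filters.min_maf: must be in [0, 0.5)")
    bad_stage = set(cfg["stages"]) - _VALID_STAGES
    for s in sorted(bad_stage):
        errors.append(f"stages: unknown stage {s!r}")
    if cfg["vcf"] is None and cfg["preset"] not in coalsim.PRESET_NAMES:
        errors.append(f"preset: unknown preset {cfg['preset']!r}")
    if (cfg["vcf"] is None) != (cfg["popmap"] is None):
        errors.append("vcf/popmap: give both or neither")
    if errors:
        raise ConfigError(errors)
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(config, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the report dict; writes per-stage TSVs, ``report.json``,
    ``manifest.json`` and ``log.txt`` under the output directory.  On a
    stage failure the exception is re-raised naming the stage, with
    completed outputs left in place.
    """
    cfg = validate_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    log: list[str] = []
    stages = list(cfg["stages"])
    if cfg["direction"]["enabled"] and "direction" not in stages:
        stages.append("direction")
    stage = "init"
    try:
        # --- ingest or simulate
        if cfg["vcf"] is not None:
            stage = "ingest"
            gm = genotypes.read_vcf(cfg["vcf"], cfg["popmap"])
            log.append(f"ingest: {gm.n_sites} biallelic SNPs, "
                       f"excluded {gm.excluded}")
        else:
            stage = "simulate"
            model = coalsim.scenario_preset(cfg["preset"], phi=cfg["phi"])
            ds = coalsim.simulate(model, cfg["sampling"], n_loci=cfg["n_loci"],
                                  locus_length=cfg["locus_length"],
                                  seed=cfg["seed"], n_contigs=cfg["n_contigs"])
            deg = cfg["degrade"]
            if deg["missing_rate"] > 0:
                ds = coalsim.degrade(ds, deg["missing_rate"], deg["qual"],
                                     seed=cfg["seed"] + 1)
            else:
                ds = coalsim.degrade(ds, 0.0, deg["qual"], seed=cfg["seed"] + 1)
            gm = genotypes.from_simulated(ds)
            log.append(f"simulate: preset={cfg['preset']} phi={cfg['phi']} "
                       f"sites={gm.n_sites}")
            report["simulate"] = {"n_sites": gm.n_sites,
                                  "n_samples": gm.n_samples}
        if "filter" in stages:
            stage = "filter"
            f = cfg["filters"]
            gm = genotypes.filter_variants(gm, f["max_missing"], f["min_qual"],
                                           f["min_maf"])
            report["filter"] = {"n_retained": gm.n_sites,
                                "excluded": gm.excluded}
            log.append(f"filter: retained {gm.n_sites}, excluded {gm.excluded}")
        stage = "freqs"
        roles = cfg["roles"]
        ft = genotypes.allele_freqs(gm, roles=roles, polarize_by_outgroup=True)
        report["freqs"] = {"n_sites": ft.n_sites, "dropped": ft.dropped}
        log.append(f"freqs: {ft.n_sites} polarized sites, dropped {ft.dropped}")
        windows = genotypes.make_windows(gm.contigs, cfg["window_width"])
        if "dstat" in stages:
            stage = "dstat"
            d = introgression.patterson_d(ft, block_size_snps=cfg["block_size_snps"])
            report["dstat"] = {
                "D": d.d, "Z": d.z, "se": d.se, "abba": d.abba, "baba": d.baba,
                "n_blocks": d.n_blocks, "significant": bool(d.significant),
            }
            per_chrom = introgression.chrom_scan_d(
                ft, block_size_snps=cfg["block_size_snps"])
            rows = [{"contig": r.contig, "D": r.d, "Z": r.z, "se": r.se,
                     "n_blocks": r.n_blocks, "status": r.status}
                    for r in per_chrom]
            pd.DataFrame(rows).to_csv(out / "dstat_by_contig.tsv", sep="\t",
                                      index=False, float_format="%.6g")
            report["dstat"]["n_significant_contigs"] = int(
                sum(1 for r in per_chrom if r.status == "ok" and r.z > 3))
            log.append(f"dstat: D={d.d:.4f} Z={d.z:.2f}")
        if "fdm" in stages:
            stage = "fdm"
            fdm, skipped = introgression.fdm_windows(
                ft, windows=windows, min_sites=cfg["min_sites_per_window"])
            if fdm:
                thr, outliers = introgression.fdm_outliers(fdm, cfg["quantile"])
                vals = [r.fdm for r in fdm]
                report["fdm"] = {
                    "n_windows": len(fdm), "mean": float(np.mean(vals)),
                    "outlier_threshold": thr, "n_outliers": len(outliers),
                    "skipped": skipped,
                }
                pd.DataFrame(
                    [{"contig": r.window.contig, "start": r.window.start,
                      "end": r.window.end, "n_sites": r.n_sites_used,
                      "fdm": r.fdm} for r in fdm]
                ).to_csv(out / "fdm.tsv", sep="\t", index=False,
                         float_format="%.6g")
                log.append(f"fdm: {len(fdm)} windows, mean "
                           f"{report['fdm']['mean']:.4f}")
            else:
                report["fdm"] = {"n_windows": 0, "skipped": skipped}
                log.append("fdm: no windows passed the site minimum")
        if "f3" in stages:
            stage = "f3"
            triple = (roles["P2"], roles["P3"], roles["P1"])
            r3 = introgression.f3(ft, triple, block_size_snps=cfg["f3_block_size"])
            report["f3"] = {"target": triple[0], "sources": list(triple[1:]),
                            "f3": r3.f3, "Z": r3.z, "call": r3.call}
            log.append(f"f3({triple[0]}; {triple[1]}, {triple[2]}) = "
                       f"{r3.f3:.4f}, Z = {r3.z:.2f}")
        if "windows" in stages:
            stage = "windows"
            pops = [roles["P2"], roles["P3"]]
            ws = popgen.window_diversity(gm, populations=pops, windows=windows)
            frame = popgen.window_stats_frame(ws)
            frame.to_csv(out / "windows.tsv", sep="\t", index=False,
                         float_format="%.6g")
            key = f"{pops[0]}|{pops[1]}"
            report["windows"] = {
                "n_windows": len(ws),
                "mean_fst": float(np.nanmean([w.fst.get(key, np.nan) for w in ws])),
                "mean_dxy": float(np.nanmean([w.dxy.get(key, np.nan) for w in ws])),
            }
            log.append(f"windows: {len(ws)} windows "
                       f"(mean FST {report['windows']['mean_fst']:.3f})")
        obs = None
        if "sfs" in stages or "direction" in stages:
            stage = "sfs"
            pair = tuple(cfg["sfs_pair"] or (roles["P2"], roles["P3"]))
            obs = demography.joint_sfs(gm, pair, polarized=True)
            np.savetxt(out / "sfs.tsv", obs.grid, delimiter="\t", fmt="%.6g")
            report["sfs"] = {"pair": list(pair), "total": obs.total,
                             "shape": list(obs.grid.shape)}
            log.append(f"sfs: {pair} total {obs.total:.0f}")
        if "direction" in stages and cfg["direction"]["enabled"]:
            stage = "direction"
            dcfg = cfg["direction"]
            base = dcfg["base"] or {"ne": 10_000.0, "t_split": 100_000.0,
                                    "m": 1e-5}
            res = demography.direction_test(
                obs, base, pulse_time=dcfg["pulse_time"], seed=cfg["seed"])
            report["direction"] = {
                "supported": res["supported"], "delta_cl": res["delta_cl"],
                "phi": {k: f.params.get("phi") for k, f in res["fits"].items()},
            }
            log.append(f"direction: {res['supported']} "
                       f"(delta CL {res['delta_cl']:.1f})")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "introflow_version": __version__,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return report
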