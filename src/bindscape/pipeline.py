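"""End-to-end pipeline: normalize -> CFR -> scan -> threshold -> landscape ->
chromatin -> report.

The configuration is a flat mapping (or a ``key = value`` text file) naming
the input files and the handful of analysis parameters.  Every table is
written as TSV with a header; a JSON run manifest records parameters, seeds
and input checksums so a run is reproducible and auditable.  Identical config
plus seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .chromatin import (
    OpenChromatinSet,
    build_accessibility_records,
    cfr_vs_dhs,
    fraction_closed_by_decile,
)
from .core import (
    GenomicInterval,
    read_bed,
    read_bedgraph,
    read_fasta,
    write_bed,
)
from .motifs import (
    PWM,
    count_unit_gap_pairs,
    determine_threshold,
    region_best_score,
    sample_negative_set,
    scan_sequence,
    spacing_by_decile,
    window_densities,
)
from .occupancy import compute_cfr, normalize_genotype, rudimentary_peak_find
from .stats import extreme_decile_compare

log = logging.getLogger("bindscape")

DEFAULTS = {
    "background_cutoff": 20.0,
    "background_min_gap": 25,
    "cfr_cap": 300.0,
    "min_alt_coverage": 130.0,
    "gc_tol": 0.05,
    "alpha": 0.05,
    "max_distance": 40,
    "scan_threshold": "auto",
    "fallback_threshold": -20.0,
    "seed": 0,
    "skip_chromatin": False,
    "symmetric_fusion": False,
}

_REQUIRED_INPUTS = [
    "genome",
    "pwm",
    "regions",
    "chrom_sizes",
    "ref_rep1",
    "ref_rep2",
    "alt_rep1",
    "alt_rep2",
    "control",
]


class ConfigurationError(ValueError):
    pass


def read_config(path) -> Dict[str, object]:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    cfg: Dict[str, object] = {}
    base = Path(path).parent
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"malformed config line: {raw!r}")
        key, value = (t.strip() for t in line.split("=", 1))
        cfg[key] = value
    # resolve relative input paths against the config file location
    for key in _REQUIRED_INPUTS + ["dhs_open", "dhs_signal"]:
        if key in cfg and not Path(str(cfg[key])).is_absolute():
            cfg[key] = str(base / str(cfg[key]))
    return cfg


def _coerce(cfg: Dict[str, object]) -> Dict[str, object]:
    out = dict(DEFAULTS)
    out.update(cfg)
    for key in ("background_cutoff", "cfr_cap", "min_alt_coverage", "gc_tol",
                "alpha", "fallback_threshold"):
        out[key] = float(out[key])
    for key in ("background_min_gap", "max_distance", "seed"):
        out[key] = int(out[key])
    for key in ("skip_chromatin", "symmetric_fusion"):
        if isinstance(out[key], str):
            out[key] = out[key].lower() in ("1", "true", "yes")
    if out["scan_threshold"] != "auto":
        out["scan_threshold"] = float(out["scan_threshold"])
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    """In-memory results of a full run (tables are also written to outdir)."""

    scale_factors: pd.DataFrame
    cfr_table: pd.DataFrame
    threshold: Optional[int]
    threshold_table: pd.DataFrame
    landscape_table: pd.DataFrame
    spacing_matrix: pd.DataFrame
    tests: Dict[str, dict] = field(default_factory=dict)
    accessibility_table: Optional[pd.DataFrame] = None
    closed_fraction_by_decile: Optional[np.ndarray] = None
    outdir: Optional[Path] = None


def _write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def run_pipeline(config, outdir) -> PipelineResult:
    """Execute the full analysis; see module docstring for the stage order."""
    if isinstance(config, (str, Path)):
        config = read_config(config)
    cfg = _coerce(dict(config))
    missing = [k for k in _REQUIRED_INPUTS if k not in cfg]
    if missing:
        raise ConfigurationError(f"missing required inputs: {missing}")
    for key in _REQUIRED_INPUTS:
        if not Path(str(cfg[key])).exists():
            raise ConfigurationError(f"input file not found: {key} = {cfg[key]}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_lengths: Dict[str, int] = {}
    for line in Path(str(cfg["chrom_sizes"])).read_text().splitlines():
        if line.strip():
            c, n = line.split("\t")[:2]
            chrom_lengths[c] = int(n)

    log.info("loading inputs")
    genome = read_fasta(cfg["genome"])
    pwm = PWM.from_tsv(cfg["pwm"])
    regions = read_bed(cfg["regions"])
    tracks = {
        name: read_bedgraph(cfg[name], chrom_lengths)
        for name in ("ref_rep1", "ref_rep2", "alt_rep1", "alt_rep2", "control")
    }

    # --- stage 1: normalization -------------------------------------------
    log.info("normalization: background peaks at cutoff %s", cfg["background_cutoff"])
    bg_peaks = rudimentary_peak_find(
        tracks["control"],
        cutoff=cfg["background_cutoff"],
        min_gap=cfg["background_min_gap"],
    )
    if not bg_peaks:
        raise ConfigurationError("no background peaks found in the control track")
    norm_ref, sf_ref = normalize_genotype(
        tracks["ref_rep1"], tracks["ref_rep2"], tracks["control"], regions, bg_peaks,
        symmetric_fusion=cfg["symmetric_fusion"],
    )
    norm_alt, sf_alt = normalize_genotype(
        tracks["alt_rep1"], tracks["alt_rep2"], tracks["control"], regions, bg_peaks,
        symmetric_fusion=cfg["symmetric_fusion"],
    )
    scale_df = pd.DataFrame(
        [
            {"genotype": "ref", "m": sf_ref.m, "m_prime": sf_ref.m_prime,
             "n_peaks": sf_ref.n_replicate_points,
             "n_background_peaks": sf_ref.n_background_peaks},
            {"genotype": "alt", "m": sf_alt.m, "m_prime": sf_alt.m_prime,
             "n_peaks": sf_alt.n_replicate_points,
             "n_background_peaks": sf_alt.n_background_peaks},
        ]
    )

    # --- stage 2: CFR ------------------------------------------------------
    records = compute_cfr(
        regions, norm_ref, norm_alt,
        cap=cfg["cfr_cap"], min_alt_coverage=cfg["min_alt_coverage"],
    )
    n_capped = sum(r.capped for r in records)
    if n_capped:
        log.warning("%d region(s) capped at CFR = %s", n_capped, cfg["cfr_cap"])
    cfr_df = pd.DataFrame(
        {
            "chrom": [r.region.chrom for r in records],
            "start": [r.region.start for r in records],
            "end": [r.region.end for r in records],
            "id": [r.region.id for r in records],
            "cov_ref": [r.cov_ref for r in records],
            "cov_alt": [r.cov_alt for r in records],
            "cfr": [r.cfr for r in records],
            "capped": [r.capped for r in records],
        }
    )

    # --- stage 3: scan + threshold ----------------------------------------
    log.info("negative-set sampling (seed %s) and threshold determination", cfg["seed"])
    negatives, _cats = sample_negative_set(
        regions, genome, gc_tol=cfg["gc_tol"], seed=cfg["seed"]
    )
    pos_dens = window_densities(regions, genome, pwm)
    neg_dens = window_densities(negatives, genome, pwm)
    thr_result = determine_threshold(pos_dens, neg_dens, alpha=cfg["alpha"])
    if cfg["scan_threshold"] == "auto":
        threshold = thr_result.threshold
        if threshold is None:
            threshold = cfg["fallback_threshold"]
            log.warning(
                "no significant score window; falling back to threshold %s", threshold
            )
    else:
        threshold = cfg["scan_threshold"]

    # --- stage 4: landscape -----------------------------------------------
    site_map = {}
    for region in regions:
        rid = region.id or f"{region.chrom}:{region.start}-{region.end}"
        site_map[rid] = scan_sequence(
            pwm, genome.fetch(region), float(threshold), region_id=rid
        )
    landscape_df = cfr_df[["chrom", "start", "end", "id", "cfr", "capped"]].copy()
    landscape_df["best_score"] = [
        region_best_score(r, genome, pwm) for r in regions
    ]
    landscape_df["site_count"] = [len(site_map[i]) for i in landscape_df["id"]]
    landscape_df["site_density_per_kb"] = [
        len(site_map[i]) * 1000.0 / (e - s)
        for i, s, e in zip(landscape_df["id"], landscape_df["start"], landscape_df["end"])
    ]
    landscape_df["unit_gap_pairs"] = [
        count_unit_gap_pairs(site_map[i], pwm.length) for i in landscape_df["id"]
    ]
    spacing = spacing_by_decile(
        records, site_map, pwm.length, max_distance=cfg["max_distance"]
    )

    class _Rec:  # light adapter: decile machinery expects .region and value attrs
        __slots__ = ("region", "cfr", "best_score", "density", "pairs")

        def __init__(self, region, cfr, best_score, density, pairs):
            self.region, self.cfr = region, cfr
            self.best_score, self.density, self.pairs = best_score, density, pairs

    recs = [
        _Rec(r.region, r.cfr, bs, dens, pr)
        for r, bs, dens, pr in zip(
            records,
            landscape_df["best_score"],
            landscape_df["site_density_per_kb"],
            landscape_df["unit_gap_pairs"],
        )
    ]
    tests = {
        "cfr_by_best_score": vars(
            extreme_decile_compare(recs, key=lambda r: r.best_score, value=lambda r: r.cfr)
        ),
        "cfr_by_site_density": vars(
            extreme_decile_compare(recs, key=lambda r: r.density, value=lambda r: r.cfr)
        ),
        "cfr_by_unit_gap_pairs": vars(
            extreme_decile_compare(recs, key=lambda r: r.pairs, value=lambda r: r.cfr)
        ),
    }

    # --- stage 5: chromatin (optional) ------------------------------------
    access_df = None
    closed_frac = None
    if not cfg["skip_chromatin"] and "dhs_open" in cfg and "dhs_signal" in cfg:
        open_set = OpenChromatinSet(read_bed(cfg["dhs_open"]), source="dhs")
        dhs_track = read_bedgraph(cfg["dhs_signal"], chrom_lengths)
        acc = build_accessibility_records(records, open_set, dhs_track)
        corr = cfr_vs_dhs(acc)
        closed_frac = fraction_closed_by_decile(acc)
        tests["cfr_vs_dhs_pearson"] = {
            **vars(corr.pearson), "r_squared": corr.r_squared
        }
        tests["cfr_by_dhs_extreme_deciles"] = vars(corr.extreme_decile)
        access_df = pd.DataFrame(
            {
                "chrom": [a.region.chrom for a in acc],
                "start": [a.region.start for a in acc],
                "end": [a.region.end for a in acc],
                "id": [a.region.id for a in acc],
                "cfr": [a.cfr for a in acc],
                "open": [a.open for a in acc],
                "dhs_signal": [a.dhs_signal for a in acc],
            }
        )

    # --- stage 6: report ---------------------------------------------------
    _write_tsv(scale_df, outdir / "scale_factors.tsv")
    _write_tsv(cfr_df, outdir / "cfr_table.tsv")
    write_bed(bg_peaks, outdir / "background_peaks.bed")
    _write_tsv(thr_result.table, outdir / "threshold_report.tsv")
    _write_tsv(landscape_df, outdir / "landscape_table.tsv")
    spacing.index.name = "decile"
    _write_tsv(spacing, outdir / "spacing_by_decile.tsv", index=True)
    if access_df is not None:
        _write_tsv(access_df, outdir / "accessibility_table.tsv")
        closed_df = pd.DataFrame(
            {"decile": range(10), "closed_fraction": closed_frac}
        )
        _write_tsv(closed_df, outdir / "closed_fraction_by_decile.tsv")

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    manifest = {
        "bindscape_version": __version__,
        "parameters": {
            k: v for k, v in cfg.items() if k not in _REQUIRED_INPUTS
        },
        "threshold": None if thr_result.threshold is None else int(thr_result.threshold),
        "threshold_used": float(threshold),
        "n_regions": len(regions),
        "n_capped": int(n_capped),
        "inputs": {k: _sha256(cfg[k]) for k in _REQUIRED_INPUTS},
        "tests": _clean(tests),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        scale_factors=scale_df,
        cfr_table=cfr_df,
        threshold=thr_result.threshold,
        threshold_table=thr_result.table,
        landscape_table=landscape_df,
        spacing_matrix=spacing,
        tests=tests,
        accessibility_table=access_df,
        closed_fraction_by_decile=closed_frac,
        outdir=outdir,
    )
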