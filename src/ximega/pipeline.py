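"""End-to-end analysis runs: synthesize -> balance -> PC1/insulation ->
classify -> report.

A run is described by a declarative config (YAML-compatible dict / file);
outputs are deterministic given (config, seed): the single global seed
fans out to per-stage seeds through a stable hash, so any stage re-run in
isolation reproduces its outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic as _allelic
from . import insulation as _insulation
from . import megadomain as _mega
from . import synthetic_data as _synth
from .errors import ParameterError
from .matrix import kr_balance, pearson_correlation, sqrt_vc_balance
from .track_io import write_bed, write_bedgraph

__all__ = [
    "RunConfig",
    "derive_seed",
    "run_megadomain_analysis",
    "run_insulation_analysis",
    "run_allelic_analysis",
]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Declarative run description.

    ``megadomain`` / ``insulation`` / ``allelic`` each hold the synthesis
    parameters and thresholds for that analysis; absent sections are
    skipped by the corresponding runner.
    """

    seed: int = 0
    outdir: str = "ximega_out"
    megadomain: dict = field(default_factory=dict)
    insulation: dict = field(default_factory=dict)
    allelic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def ensure_outdir(self) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _xi_params(section: dict, seed: int, **overrides) -> _synth.XiModelParams:
    kw = dict(section.get("synthesis", {}))
    kw.update(overrides)
    kw.setdefault("seed", seed)
    if "tad_borders" in kw:
        kw["tad_borders"] = tuple(kw["tad_borders"])
    return _synth.XiModelParams(**kw)


def run_megadomain_analysis(cfg: RunConfig) -> dict:
    """PC1 tracks, border slopes, sharp-transition calls and the mixing
    regression for every configured condition; returns the summary dict
    (also written to ``megadomain_summary.json``)."""
    out = cfg.ensure_outdir()
    sec = cfg.megadomain
    conditions = sec.get("conditions", {"negative": 0.0, "positive": 1.0})
    flank_bins = sec.get("flank_bins", 10)
    threshold = sec.get("transition_threshold", 3.0)
    summary = {"conditions": {}, "seed": cfg.seed}
    border = None
    for name, fraction in conditions.items():
        stage_seed = derive_seed(cfg.seed, f"megadomain:{name}")
        params = _xi_params(sec, stage_seed)
        border = params.border_bin
        point = _synth.simulate_time_course(params, [float(fraction)])[0]
        balanced = kr_balance(point.matrix)
        corr = pearson_correlation(balanced)
        track = _mega.pc1(corr, border_bin=border)
        slope = _mega.pc1_slope(track, border)
        decision, stat = _mega.sharp_transition_test(track, border,
                                                     flank_bins=flank_bins,
                                                     threshold=threshold)
        write_bedgraph(out / f"pc1_{name}.bedgraph", track.chrom, track.scores,
                       track.bin_size, track.start_coord)
        summary["conditions"][name] = {
            "positive_fraction": float(fraction),
            "pc1_slope": slope,
            "sharp_transition": decision,
            "transition_statistic": stat,
            "explained_fraction": track.explained_fraction,
        }
    fractions = sec.get("mixing_fractions")
    if fractions:
        slopes = []
        for f in fractions:
            stage_seed = derive_seed(cfg.seed, f"megadomain:mix:{f}")
            params = _xi_params(sec, stage_seed)
            point = _synth.simulate_time_course(params, [float(f)])[0]
            balanced = kr_balance(point.matrix)
            track = _mega.pc1(pearson_correlation(balanced), border_bin=params.border_bin)
            slopes.append(_mega.pc1_slope(track, params.border_bin))
        fit = _mega.mixing_regression(fractions, slopes)
        summary["mixing"] = {
            "fractions": list(map(float, fractions)),
            "slopes": slopes,
            "intercept": fit.intercept,
            "slope_coefficient": fit.slope_coefficient,
            "r_squared": fit.r_squared,
            "residual_sd": fit.residual_sd,
            "detection_limit": _mega.detection_limit(fit,
                                                     k_sd=sec.get("k_sd", 2.0)),
        }
        summary["estimated_fractions"] = {
            name: _mega.estimate_positive_fraction(fit, info["pc1_slope"])["estimate"]
            for name, info in summary["conditions"].items()
        }
    _dump_json(out / "megadomain_summary.json", summary)
    return summary


def run_insulation_analysis(cfg: RunConfig) -> dict:
    """Insulation tracks, boundary calls and the pairwise F-test matrix for
    every configured condition (p < 0.05 flagged significant)."""
    out = cfg.ensure_outdir()
    sec = cfg.insulation
    conditions = sec.get("conditions", {"default": {}})
    ins_params = _insulation.InsulationParams(
        square_span=sec.get("square_span", 125_000),
        delta_span=sec.get("delta_span", 75_000),
        edge_exclude_bins=sec.get("edge_exclude_bins", 6))
    min_depth = sec.get("min_depth", 0.1)
    alpha = sec.get("alpha", 0.05)
    tracks = {}
    summary = {"conditions": {}, "seed": cfg.seed}
    for name, overrides in conditions.items():
        stage_seed = derive_seed(cfg.seed, f"insulation:{name}")
        params = _xi_params(sec, stage_seed, **overrides)
        matrix = _synth.simulate_contact_matrix(params)
        balanced = sqrt_vc_balance(matrix)
        track = _insulation.insulation_track(balanced, ins_params)
        boundaries = _insulation.call_boundaries(track, min_depth=min_depth)
        tracks[name] = track
        write_bedgraph(out / f"insulation_{name}.bedgraph", track.chrom,
                       track.scores, track.bin_size, track.start_coord)
        write_bed(out / f"boundaries_{name}.bed",
                  [(track.chrom,
                    track.start_coord + b * track.bin_size,
                    track.start_coord + (b + 1) * track.bin_size,
                    f"boundary_{b}", f"{depth:.4g}") for b, depth in boundaries])
        summary["conditions"][name] = {
            "n_scored_bins": int(track.mask.sum()),
            "score_variance": float(np.var(track.unmasked_scores(), ddof=1)),
            "boundaries": [int(b) for b, _ in boundaries],
        }
    rows = []
    names = list(conditions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = _insulation.variance_f_test(tracks[a], tracks[b])
            rows.append({"condition_a": a, "condition_b": b,
                         "variance_a": res.variance_a, "variance_b": res.variance_b,
                         "f_statistic": res.f_statistic, "p_value": res.p_value,
                         "significant": res.p_value < alpha})
    pd.DataFrame(rows, columns=["condition_a", "condition_b", "variance_a",
                                "variance_b", "f_statistic", "p_value",
                                "significant"]).to_csv(
        out / "insulation_f_tests.tsv", sep="\t", index=False)
    summary["f_tests"] = rows
    _dump_json(out / "insulation_summary.json", summary)
    return summary


def run_allelic_analysis(cfg: RunConfig) -> dict:
    """Peak classification, restored/concordant peaks, escapee calls and
    distribution comparisons on synthetic or supplied allelic tables."""
    out = cfg.ensure_outdir()
    sec = cfg.allelic
    wt_kw = dict(sec.get("wt", {}))
    wt_kw.setdefault("genotype", "wt")
    wt_kw.setdefault("seed", derive_seed(cfg.seed, "allelic:wt"))
    mut_kw = dict(sec.get("mut", {}))
    mut_kw.setdefault("genotype", "mut")
    mut_kw.setdefault("seed", derive_seed(cfg.seed, "allelic:mut"))
    wt_table, _ = _synth.simulate_allelic_peaks(_synth.AllelicTableParams(**wt_kw))
    mut_table, _ = _synth.simulate_allelic_peaks(_synth.AllelicTableParams(**mut_kw))

    classified = _allelic.classify_peaks(
        wt_table, min_allelic_reads=sec.get("min_allelic_reads", 10),
        ratio_threshold=sec.get("ratio_threshold", 1 / 3))
    classified.to_csv(out / "peak_classes.tsv", sep="\t", index=False)
    class_counts = classified["peak_class"].value_counts().to_dict()

    per_rep, concordant = _allelic.restored_peaks(
        wt_table, mut_table, ratio=sec.get("restored_ratio", 0.5))
    per_rep.to_csv(out / "restored_peaks.tsv", sep="\t", index=False)

    combined = pd.concat([wt_table, mut_table], ignore_index=True)
    escapees = _allelic.classify_escapees(
        combined, xi_fraction=sec.get("xi_fraction", 0.10),
        min_allelic_reads=sec.get("escapee_min_reads", 12))
    escapees.to_csv(out / "escapees.tsv", sep="\t")

    compare = _allelic.xi_expression_density_compare(wt_table, mut_table)

    summary = {
        "seed": cfg.seed,
        "peak_class_counts": {k: int(v) for k, v in class_counts.items()},
        "n_restored_records": int(per_rep["restored"].sum()) if len(per_rep) else 0,
        "n_concordant": len(concordant),
        "escapee_counts": {g: int(escapees[g].sum()) for g in escapees.columns},
        "shared_escapees": len(escapees.attrs.get("overlap", [])),
        "xi_expression_compare": compare,
    }
    _dump_json(out / "allelic_summary.json", summary)
    return summary
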