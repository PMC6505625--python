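"""Stage orchestration: run the analysis stages over files on disk.

Each stage reads plain-text inputs (line-delimited JSON corpus, TSV lexicon),
writes CSV tables to an output directory, and records a manifest
(``<stage>.manifest.json``) listing inputs, parameters, seed and output
hashes.  Reruns with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filtering, hedonometer, locales, mobility, trajnorm, wordshift
from .corpus import Corpus, read_messages, write_messages, write_table
from .lexicon import Lexicon, load_packaged_lexicon, read_lexicon
from .synthetic import PopulationConfig, generate_population

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_stage", "STAGES"]


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run; defaults follow the analysis
    conventions (30-message activity threshold, 100 m / 10-message locales,
    neutral-band width 1, 10 equal-population bins)."""

    corpus: str = "corpus.jsonl"
    lexicon: str | None = None  # None -> packaged fixture
    outdir: str = "out"
    seed: int = 0
    min_messages: int = 30
    bot_fraction: float = 0.5
    locale_radius_m: float = 100.0
    locale_min_count: int = 10
    delta: float = 1.0
    bins: int = 10
    heavy_threshold: int = 800
    shape_threshold: int = 50  # more-than-50-locations eligibility, strict
    corridor_half_width: float = 1.0
    grid: str = "x=-6:6,y=-4:4,cell=0.1"  # density-grid extents, normalized units
    bot_keywords: str | None = None  # path to a keyword file, one per line
    n_individuals: int = 200  # generate stage
    msgs_median: float = 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def load_lexicon(self) -> Lexicon:
        if self.lexicon is None:
            return load_packaged_lexicon(neutral_delta=self.delta)
        return read_lexicon(self.lexicon, neutral_delta=self.delta)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, inputs: list, params: dict, outputs: list):
    manifest = {
        "stage": stage,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "parameters": params,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    path = outdir / f"{stage}.manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _require(path: Path, what: str):
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact for {what}: {path}")


def _parse_grid(expr: str):
    """Parse "x=-6:6,y=-4:4,cell=0.1" into (x_range, y_range, cell)."""
    parts = dict(p.split("=", 1) for p in expr.split(","))
    xr = tuple(float(v) for v in parts["x"].split(":"))
    yr = tuple(float(v) for v in parts["y"].split(":"))
    return xr, yr, float(parts["cell"])


def _bot_keywords(cfg: PipelineConfig):
    if cfg.bot_keywords is None:
        return filtering.BOT_KEYWORDS
    path = Path(cfg.bot_keywords)
    _require(path, "bot keyword list")
    return frozenset(
        w.strip().lower() for w in path.read_text().splitlines() if w.strip()
    )


def _load_corpus(cfg: PipelineConfig) -> Corpus:
    path = Path(cfg.corpus)
    _require(path, "corpus")
    return read_messages(path)


def stage_generate(cfg: PipelineConfig) -> list:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = PopulationConfig(n_individuals=cfg.n_individuals, msgs_median=cfg.msgs_median)
    corpus, truth = generate_population(pop, seed=cfg.seed)
    corpus_path = Path(cfg.corpus)
    write_messages(corpus, corpus_path)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "zipf_exponent": truth.zipf_exponent,
                "bot_ids": sorted(truth.bot_ids),
                "n_checkins": len(truth.checkin_ids),
                "users": {
                    u: {
                        "locale_probs": t.locale_probs.tolist(),
                        "structure_gyradius_m": t.structure_gyradius_m,
                        "is_bot": t.is_bot,
                        "is_longhaul": t.is_longhaul,
                    }
                    for u, t in truth.users.items()
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    _write_manifest(
        outdir, "generate", [], {"seed": cfg.seed, "n_individuals": cfg.n_individuals}, [corpus_path, truth_path]
    )
    return [corpus_path, truth_path]


def stage_filter(cfg: PipelineConfig) -> list:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus = _load_corpus(cfg)
    report = filtering.apply_filters(
        corpus,
        min_messages=cfg.min_messages,
        bot_keywords=_bot_keywords(cfg),
        bot_fraction=cfg.bot_fraction,
    )
    filtered_path = outdir / "filtered.jsonl"
    write_messages(report.corpus, filtered_path)
    report_path = outdir / "filter_report.csv"
    write_table(report.summary_frame(), report_path)
    _write_manifest(
        outdir,
        "filter",
        [cfg.corpus],
        {"min_messages": cfg.min_messages, "bot_fraction": cfg.bot_fraction},
        [filtered_path, report_path],
    )
    return [filtered_path, report_path]


def _filtered_corpus(cfg: PipelineConfig) -> Corpus:
    path = Path(cfg.outdir) / "filtered.jsonl"
    _require(path, "mobility (run the filter stage first)")
    return read_messages(path)


def stage_mobility(cfg: PipelineConfig) -> list:
    outdir = Path(cfg.outdir)
    corpus = _filtered_corpus(cfg)
    summaries = mobility.summarize_corpus(corpus)
    summary_path = outdir / "user_summaries.csv"
    write_table(mobility.summaries_frame(summaries), summary_path)
    dist = mobility.per_message_distances(corpus, summaries)
    dist_path = outdir / "message_distances.csv"
    write_table(
        pd.DataFrame(
            {"message_id": corpus.frame["message_id"], "distance_m": dist}
        ),
        dist_path,
    )
    ccdf_path = outdir / "gyradius_ccdf.csv"
    write_table(
        mobility.gyradius_ccdf([s.gyradius_m for s in summaries.values()]), ccdf_path
    )
    _write_manifest(
        outdir, "mobility", [outdir / "filtered.jsonl"], {}, [summary_path, dist_path, ccdf_path]
    )
    return [summary_path, dist_path, ccdf_path]


def stage_trajnorm(cfg: PipelineConfig) -> list:
    outdir = Path(cfg.outdir)
    corpus = _filtered_corpus(cfg)
    summaries = mobility.summarize_corpus(corpus)
    profiles = locales.extract_profiles(
        corpus, cfg.locale_radius_m, cfg.locale_min_count, summaries=summaries
    )
    modes = {
        u: locales.mode_location(p)
        for u, p in profiles.items()
        if locales.mode_location(p) is not None
    }
    norms = trajnorm.normalize_population(
        corpus, summaries, mode_locations=modes, min_locations=cfg.shape_threshold
    )
    if not norms:
        raise ValueError("no users eligible for trajectory normalization")
    pooled = np.vstack([n.points for n in norms.values()])
    x_range, y_range, cell = _parse_grid(cfg.grid)
    grid = trajnorm.density_map(pooled, x_range=x_range, y_range=y_range, cell=cell)
    grid_path = outdir / "density_grid.csv"
    write_table(grid.to_frame(), grid_path)
    corr_path = outdir / "corridor_profile.csv"
    write_table(
        trajnorm.corridor_profile(
            pooled, cfg.corridor_half_width, x_range=x_range, cell=cell
        ),
        corr_path,
    )
    iso_path = outdir / "isotropy_by_decile.csv"
    k = min(10, len(norms))
    write_table(trajnorm.isotropy_by_gyradius(norms, summaries, k=k), iso_path)
    _write_manifest(
        outdir,
        "trajnorm",
        [outdir / "filtered.jsonl"],
        {"shape_threshold": cfg.shape_threshold, "corridor_half_width": cfg.corridor_half_width},
        [grid_path, corr_path, iso_path],
    )
    return [grid_path, corr_path, iso_path]


def stage_locales(cfg: PipelineConfig) -> list:
    outdir = Path(cfg.outdir)
    corpus = _filtered_corpus(cfg)
    heavy = filtering.apply_activity_threshold(corpus, cfg.heavy_threshold)
    if heavy.n_users == 0:
        logger.warning(
            "no users reach the heavy threshold %d; using all filtered users",
            cfg.heavy_threshold,
        )
        heavy = corpus
    profiles = locales.extract_profiles(heavy, cfg.locale_radius_m, cfg.locale_min_count)
    rows = []
    for uid, prof in profiles.items():
        for loc in prof.locales:
            rows.append(
                {
                    "user_id": uid,
                    "rank": loc.rank,
                    "count": loc.count,
                    "probability": loc.count / prof.n_messages,
                    "radius_m": loc.radius_m,
                }
            )
    loc_path = outdir / "locales.csv"
    write_table(
        pd.DataFrame(rows, columns=["user_id", "rank", "count", "probability", "radius_m"]),
        loc_path,
    )
    rank_prob = locales.pooled_rank_probabilities(profiles)
    rank_path = outdir / "rank_probabilities.csv"
    write_table(rank_prob, rank_path)
    fit = locales.fit_zipf(rank_prob)
    fit_path = outdir / "zipf_fit.csv"
    write_table(
        pd.DataFrame(
            [
                {
                    "slope": fit.params[1],
                    "intercept": fit.params[0],
                    "slope_se": fit.bse[1],
                    "r_squared": fit.rsquared,
                    "n_points": int(fit.nobs),
                }
            ]
        ),
        fit_path,
    )
    diurnal_path = outdir / "diurnal_profiles.csv"
    write_table(locales.diurnal_profiles(heavy, profiles), diurnal_path)
    _write_manifest(
        outdir,
        "locales",
        [outdir / "filtered.jsonl"],
        {
            "radius_m": cfg.locale_radius_m,
            "min_count": cfg.locale_min_count,
            "heavy_threshold": cfg.heavy_threshold,
        },
        [loc_path, rank_path, fit_path, diurnal_path],
    )
    return [loc_path, rank_path, fit_path, diurnal_path]


def stage_happiness(cfg: PipelineConfig) -> list:
    outdir = Path(cfg.outdir)
    if cfg.lexicon is not None:
        _require(Path(cfg.lexicon), "happiness")
    lexicon = cfg.load_lexicon()
    corpus = _filtered_corpus(cfg)
    summaries = mobility.summarize_corpus(corpus)
    dist = mobility.per_message_distances(corpus, summaries)
    eligible = filtering.sentiment_eligible(corpus.frame, set())
    sub = corpus.frame[eligible]
    trend_d = hedonometer.happiness_by_distance(
        sub["text"].tolist(), dist[eligible.to_numpy()].to_numpy(), lexicon, k=cfg.bins
    )
    td_path = outdir / "happiness_by_distance.csv"
    write_table(trend_d.table, td_path)

    user_texts = {
        uid: g["text"].tolist() for uid, g in sub.groupby("user_id", sort=True)
    }
    user_rg = {u: s.gyradius_m for u, s in summaries.items()}
    trend_g = hedonometer.happiness_by_gyradius(user_texts, user_rg, lexicon, k=cfg.bins)
    tg_path = outdir / "happiness_by_gyradius.csv"
    write_table(trend_g.table, tg_path)

    # log-distance fit beyond the trend minimum
    t = trend_d.table.dropna(subset=["h_avg"])
    fits = []
    if len(t) >= 2:
        dip_idx = t["h_avg"].idxmin()
        min_d = t.loc[dip_idx, "distance_median"]
        above = t[t["distance_median"] >= min_d]
        if len(above) >= 2:
            fit = hedonometer.fit_log_linear(above["distance_median"], above["h_avg"])
            fits.append(
                {
                    "trend": "distance",
                    "slope_per_decade": fit.params[1],
                    "intercept": fit.params[0],
                    "n_bins": int(fit.nobs),
                }
            )
    fit_path = outdir / "happiness_log_fit.csv"
    write_table(pd.DataFrame(fits, columns=["trend", "slope_per_decade", "intercept", "n_bins"]), fit_path)

    # bin word-count files for the word-shift stage
    ref_path = outdir / "bin_nearest.counts"
    comp_path = outdir / "bin_farthest.counts"
    for path, counts in ((ref_path, trend_d.word_counts[0]), (comp_path, trend_d.word_counts[-1])):
        with open(path, "w", encoding="utf-8") as fh:
            for w, c in sorted(counts.items()):
                fh.write(f"{w}\t{c}\n")
    _write_manifest(
        outdir,
        "happiness",
        [outdir / "filtered.jsonl"],
        {"bins": cfg.bins, "delta": cfg.delta},
        [td_path, tg_path, fit_path, ref_path, comp_path],
    )
    return [td_path, tg_path, fit_path, ref_path, comp_path]


def read_counts(path: str | Path) -> Counter:
    counts: Counter = Counter()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                w, c = line.rstrip("\n").split("\t")
                counts[w] += int(c)
    return counts


def stage_wordshift(cfg: PipelineConfig, ref: str | None = None, comp: str | None = None) -> list:
    outdir = Path(cfg.outdir)
    ref_path = Path(ref) if ref else outdir / "bin_nearest.counts"
    comp_path = Path(comp) if comp else outdir / "bin_farthest.counts"
    _require(ref_path, "wordshift reference counts")
    _require(comp_path, "wordshift comparison counts")
    lexicon = cfg.load_lexicon()
    result = wordshift.word_shift(read_counts(ref_path), read_counts(comp_path), lexicon)
    ranked_path = outdir / "wordshift_ranked.csv"
    write_table(wordshift.rank_contributions(result), ranked_path)
    balance_path = outdir / "wordshift_balance.csv"
    write_table(wordshift.type_balance(result), balance_path)
    sizes_path = outdir / "wordshift_sizes.csv"
    write_table(
        pd.DataFrame(
            [
                {
                    "h_ref": result.h_ref,
                    "h_comp": result.h_comp,
                    "delta_h": result.delta_h,
                    "ref_size": result.ref_size,
                    "comp_size": result.comp_size,
                }
            ]
        ),
        sizes_path,
    )
    _write_manifest(
        outdir,
        "wordshift",
        [ref_path, comp_path],
        {"delta": cfg.delta},
        [ranked_path, balance_path, sizes_path],
    )
    return [ranked_path, balance_path, sizes_path]


STAGES = {
    "generate": stage_generate,
    "filter": stage_filter,
    "mobility": stage_mobility,
    "trajnorm": stage_trajnorm,
    "locales": stage_locales,
    "happiness": stage_happiness,
    "wordshift": stage_wordshift,
}


def run_stage(name: str, cfg: PipelineConfig, **kwargs) -> list:
    """Run one named stage; returns the list of written output paths."""
    if name == "report":
        out = []
        for stage in ("generate", "filter", "mobility", "trajnorm", "locales", "happiness", "wordshift"):
            out.extend(STAGES[stage](cfg))
        return out
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    return STAGES[name](cfg, **kwargs)
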