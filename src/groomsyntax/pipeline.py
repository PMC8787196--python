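"""End-to-end experiment runner: fixtures, per-experiment analysis designs,
machine-readable outputs.

Each experiment mirrors one analysis design: pairwise syntax comparisons
between species-scale groups, stock-scale comparisons, variance
(variability) comparisons, within-individual repeat comparisons across
consecutive days, and the optogenetic stimulation paradigm. All outputs
are flat TSV/JSON keyed by fly/group/session id, stamped with a hash of
the run configuration, and reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as _features
from . import groupstats, stereotypy, synthetic
from .classify import chance_level as _chance_level
from .classify import classify as _classify_fn
from .ethogram import (
    Ethogram,
    denoise,
    load_cohort,
    to_bouts,
    write_ethogram,
    write_manifest,
)

logger = logging.getLogger("groomsyntax")

EXPERIMENTS = (
    "species_comparison",
    "stock_comparison",
    "variability_comparison",
    "within_individual",
    "opto",
)

FIXTURE_PRESETS = (
    "five-species-like",
    "four-stock-like",
    "variability",
    "within-individual",
    "opto",
)

#: Experiment -> fixture preset used when no manifest is supplied.
_DEFAULT_PRESET = {
    "species_comparison": "five-species-like",
    "stock_comparison": "four-stock-like",
    "variability_comparison": "variability",
    "within_individual": "within-individual",
    "opto": "opto",
}


@dataclass
class RunConfig:
    experiment: str
    input: str | None = None  # manifest path; None = generate the default preset
    output_dir: str = "groomsyntax_run"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-determining fields (where outputs are
        written does not change what is computed)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_fixtures(
    preset: str,
    out_dir: str | Path,
    seed: int = 0,
    n_flies: int | None = None,
    recording_frames: int | None = None,
) -> Path:
    """Write a small synthetic cohort (ethogram CSVs + manifest) and
    return the manifest path. Byte-identical for a fixed seed."""
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {FIXTURE_PRESETS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = recording_frames or 10_000
    rows: list[dict] = []
    ethos: list[Ethogram] = []

    if preset in ("five-species-like", "four-stock-like", "variability"):
        templates = {
            "five-species-like": synthetic.species_templates,
            "four-stock-like": synthetic.stock_templates,
            "variability": synthetic.variability_templates,
        }[preset](recording_frames=frames)
        n = n_flies or 10
        ss = np.random.SeedSequence(seed)
        for tpl, child in zip(templates, ss.spawn(len(templates))):
            ethos.extend(synthetic.simulate_population(tpl, n, child))
    elif preset == "within-individual":
        tpl = synthetic.species_templates(recording_frames=frames)[0]
        ethos = synthetic.simulate_individual_sessions(
            tpl, n_flies or 10, n_sessions=3, seed=seed
        )
    else:  # opto: three 3-min windows need a full-length recording
        frames = recording_frames or 45_000
        cfg = synthetic.opto_config(recording_frames=frames)
        ss = np.random.SeedSequence(seed)
        for i, child in enumerate(ss.spawn(n_flies or 10)):
            ethos.append(synthetic.simulate_opto_session(
                cfg, seed=child, fly_id=f"opto_f{i:02d}", group_id="opto"
            ))

    for e in ethos:
        fname = f"{e.fly_id}_{e.session_id}.csv"
        write_ethogram(e, out_dir / fname)
        row = {"fly_id": e.fly_id, "group_id": e.group_id,
               "session_id": e.session_id, "path": fname}
        if "stim_windows" in e.metadata:
            row["stim_windows"] = e.metadata["stim_windows"]
        rows.append(row)
    manifest = out_dir / "manifest.tsv"
    write_manifest(rows, manifest)
    logger.info("make_fixtures: wrote %d ethograms to %s", len(ethos), out_dir)
    return manifest


def _parse_windows(spec: str) -> list[tuple[float, float]]:
    return [tuple(float(x) for x in w.split("-")) for w in spec.split(";")]


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index=False) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_json(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


def run(cfg: RunConfig) -> dict:
    """Execute one experiment end to end; returns a report bundle
    (paths of written outputs plus headline numbers)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        return _run(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    ov = cfg.overrides
    h = cfg.config_hash
    logger.info("run: experiment=%s seed=%d hash=%s", cfg.experiment, cfg.seed, h)

    if cfg.input is not None:
        manifest = Path(cfg.input)
        if not manifest.exists():
            raise FileNotFoundError(f"manifest not found: {manifest}")
    else:
        manifest = make_fixtures(
            _DEFAULT_PRESET[cfg.experiment],
            out / "fixtures",
            seed=cfg.seed,
            n_flies=ov.get("n_flies"),
            recording_frames=ov.get("recording_frames"),
        )
    cohort_raw = load_cohort(manifest)
    cutoff = float(ov.get("denoise_cutoff_s", 0.150))
    cohort = [denoise(e, cutoff) for e in cohort_raw]
    report: dict = {"experiment": cfg.experiment, "seed": cfg.seed,
                    "config_hash": h, "n_recordings": len(cohort),
                    "outputs": {}}

    def save_tsv(name: str, df: pd.DataFrame, index=False) -> None:
        p = out / name
        _write_tsv(df, p, h, index=index)
        report["outputs"][name] = str(p)

    def save_json(name: str, obj: dict) -> None:
        p = out / name
        _write_json(obj, p, h)
        report["outputs"][name] = str(p)

    if cfg.experiment in ("species_comparison", "stock_comparison"):
        syn_by_group: dict[str, list] = {}
        for e in cohort:
            syn_by_group.setdefault(e.group_id, []).append(
                _features.syntax_vector(to_bouts(e)))
        table = groupstats.pairwise_location_tests(syn_by_group)
        save_tsv("syntax_comparisons.tsv", table)

        ent = pd.DataFrame({
            "fly_id": [e.fly_id for e in cohort],
            "group_id": [e.group_id for e in cohort],
            "entropy_nats": [
                stereotypy.entropy_rate(_features.syntax_vector(to_bouts(e))).H
                for e in cohort
            ],
        })
        save_tsv("entropy.tsv", ent)

        cls_summary = {}
        labels = [e.group_id for e in cohort]
        for family in ("proportions", "progression", "syntax", "non_grooming_only"):
            ft = _features.feature_table(cohort, family)
            res = _classify_fn(ft, labels, seed=cfg.seed, feature_set=family,
                               n_repeats=int(ov.get("cv_repeats", 10)))
            cls_summary[family] = res.accuracy
        ch = _chance_level(
            _features.feature_table(cohort, "syntax"), labels,
            n_permutations=int(ov.get("n_permutations", 100)), seed=cfg.seed,
        )
        save_json("classification.json", {
            "accuracy_by_feature_set": cls_summary,
            "chance_mean": ch["mean"], "chance_band": ch["band"],
            "n_significant_syntax_rows": int(table["significant"].sum()),
            "n_syntax_rows": int(len(table)),
        })
        report["n_comparison_rows"] = int(len(table))

    elif cfg.experiment == "variability_comparison":
        syn_by_group = {}
        for e in cohort:
            syn_by_group.setdefault(e.group_id, []).append(
                _features.syntax_vector(to_bouts(e)))
        table = groupstats.pairwise_variance_tests(syn_by_group)
        save_tsv("variance_comparisons.tsv", table)
        save_json("variance_summary.json", {
            "n_rows": int(len(table)),
            "n_significant": int(table["significant"].sum()),
            "significant_fraction": groupstats.significant_fraction(table),
        })
        report["n_comparison_rows"] = int(len(table))

    elif cfg.experiment == "within_individual":
        min_run = float(ov.get("min_run_s", 30.0))
        within_tab, within_sum = stereotypy.stereotypy_comparison(
            cohort, "within_fly_across_sessions", min_run)
        between_tab, between_sum = stereotypy.stereotypy_comparison(
            cohort, "between_fly_same_session", min_run)
        save_tsv("within_fly_distances.tsv", within_tab)
        save_tsv("between_fly_distances.tsv", between_tab)
        save_json("distance_summary.json",
                  {"within_fly": within_sum, "between_fly": between_sum})

    else:  # opto
        mdf = pd.read_csv(manifest, sep="\t", dtype=str)
        win_by_fly = {
            r["fly_id"]: _parse_windows(r["stim_windows"])
            for _, r in mdf.iterrows() if "stim_windows" in mdf.columns
        }
        min_run = float(ov.get("min_run_s", 30.0))
        ent_rows, runs = [], []
        for e in cohort:
            windows = win_by_fly.get(e.fly_id, list(synthetic.DEFAULT_OPTO_WINDOWS))
            for k, er in enumerate(stereotypy.per_window_entropy(e, windows), start=1):
                ent_rows.append({"fly_id": e.fly_id, "window": f"act{k}",
                                 "entropy_nats": er.H})
            runs.extend(stereotypy.extract_window_runs(e, windows, min_run))
        save_tsv("window_entropy.tsv", pd.DataFrame(ent_rows))
        within_tab = stereotypy.pairwise_run_distances(
            runs, "within_fly_across_sessions")
        between_tab = stereotypy.pairwise_run_distances(
            runs, "between_fly_same_session")
        save_tsv("within_fly_distances.tsv", within_tab)
        save_tsv("between_fly_distances.tsv", between_tab)
        save_json("distance_summary.json", {
            "within_fly": stereotypy.summarize_distances(within_tab),
            "between_fly": stereotypy.summarize_distances(between_tab),
            "n_runs": len(runs),
        })

    save_json("report.json", report)
    return report
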