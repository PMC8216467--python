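"""Manifest-driven analysis pipeline and fixture scenarios.

A YAML manifest describes an experiment set: kinetics groups (files,
concentrations in nM, replicate structure, condition labels) plus
derived-quantity directives (discrimination factors, rate ratios,
toehold regressions), and melt sets (files with their total strand
concentrations in uM). :func:`run_kinetics` and :func:`run_melt` turn a
manifest into tidy tables; :func:`make_fixtures` writes complete
synthetic datasets whose ground truth is recorded in a sidecar, so the
whole pipeline can be exercised and its parameter recovery measured
without any external data.

Reports are deterministic given the manifest, files and config: no
timestamps, sorted keys, fixed row order. A provenance block records
the manifest hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (load_yaml, read_melt_csv, read_well_csv, save_yaml,
                 write_melt_csv, write_well_csv)
from .kinetics import (discrimination_factor, fit_replicates,
                       fit_toehold_dependence, normalize_trace, rate_ratio)
from .melt import correct_melt, estimate_tm, fit_vant_hoff
from .simulate import (MeltSimulationSpec, TraceSimulationSpec,
                       simulate_displacement_wells, simulate_melt_wells)
from .traces import ReactionConditions
from .units import nm_to_molar, um_to_molar

__all__ = [
    "ManifestError",
    "AnalysisReport",
    "validate_manifest",
    "run_kinetics",
    "run_melt",
    "run_all",
    "make_fixtures",
    "SCENARIOS",
]


class ManifestError(ValueError):
    """Raised with the full list of manifest validation problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("manifest validation failed:\n  - " + "\n  - ".join(self.problems))


_COND_KEYS = ("in0_nM", "ai0_nM", "r0_nM")


def _conditions_from_entry(entry: dict) -> ReactionConditions:
    c = entry["conditions"]
    return ReactionConditions(
        in0=nm_to_molar(float(c["in0_nM"])), ai0=nm_to_molar(float(c["ai0_nM"])),
        r0=nm_to_molar(float(c["r0_nM"])),
        temperature=float(c.get("temperature_C", 37.0)),
    )


def validate_manifest(manifest: dict, base_dir: Path) -> None:
    """Check a manifest en masse; raises :class:`ManifestError` listing all problems."""
    problems = []
    if not isinstance(manifest, dict) or not manifest:
        raise ManifestError(["manifest is empty", "missing section: kinetics or melt"])
    if "kinetics" not in manifest and "melt" not in manifest:
        problems.append("missing section: need at least one of 'kinetics' or 'melt'")

    labels = set()
    for i, g in enumerate(manifest.get("kinetics", {}).get("groups", [])):
        where = f"kinetics.groups[{i}]"
        label = g.get("label")
        if not label:
            problems.append(f"{where}: missing label")
        elif label in labels:
            problems.append(f"{where}: duplicate label {label!r}")
        labels.add(label)
        cond = g.get("conditions", {})
        for key in _COND_KEYS:
            if key not in cond:
                problems.append(f"{where}: conditions missing {key!r}")
            elif float(cond[key]) < 0 or (key == "ai0_nM" and float(cond[key]) <= 0):
                problems.append(f"{where}: {key} must be positive")
        files = g.get("files", [])
        if not files:
            problems.append(f"{where}: no data files listed")
        for f in files:
            if not (base_dir / f).exists():
                problems.append(f"{where}: file not found: {f}")
    derived = manifest.get("kinetics", {}).get("derived", {})
    for section, keys in (("discrimination", ("match", "mismatch")),
                          ("ratios", ("numerator", "denominator"))):
        for j, d in enumerate(derived.get(section, [])):
            for key in keys:
                if d.get(key) not in labels:
                    problems.append(
                        f"kinetics.derived.{section}[{j}]: unknown group {d.get(key)!r}")
    for j, d in enumerate(derived.get("toehold_regression", [])):
        unknown = [g for g in d.get("groups", []) if g not in labels]
        if unknown:
            problems.append(f"kinetics.derived.toehold_regression[{j}]: unknown groups {unknown}")

    for i, s in enumerate(manifest.get("melt", {}).get("sets", [])):
        where = f"melt.sets[{i}]"
        if not s.get("label"):
            problems.append(f"{where}: missing label")
        entries = s.get("files", [])
        if not entries:
            problems.append(f"{where}: no melt files listed")
        for e in entries:
            if "ct_uM" not in e or float(e.get("ct_uM", 0)) <= 0:
                problems.append(f"{where}: file entry needs a positive ct_uM: {e}")
            elif not (base_dir / e["file"]).exists():
                problems.append(f"{where}: file not found: {e['file']}")
    if problems:
        raise ManifestError(problems)


@dataclass
class AnalysisReport:
    """Tidy result tables plus a provenance block.

    ``tables`` maps short names (``rates``, ``rate_summary``,
    ``discrimination``, ``ratios``, ``toehold``, ``tm``, ``thermo``) to
    DataFrames; ``provenance`` records the manifest hash, seed and
    package version so every number is traceable.
    """

    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.tables):
            self.tables[name].to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n")


def _provenance(manifest: dict, config: dict | None) -> dict:
    blob = yaml.safe_dump({"manifest": manifest, "config": config}, sort_keys=True)
    return {
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": manifest.get("seed"),
        "version": __version__,
    }


def run_kinetics(manifest: dict, base_dir, config: dict | None = None) -> AnalysisReport:
    """Normalize, fit and summarize every kinetics group in the manifest.

    Individual fit failures are recorded as unsuccessful rows and never
    abort sibling groups; derived quantities referencing a failed group
    are reported with ``error`` filled in.
    """
    base_dir = Path(base_dir)
    validate_manifest(manifest, base_dir)
    config = config or {}
    fit_kwargs = {k: config[k] for k in ("completion_threshold", "fn_cap") if k in config}

    rows, summary_rows = [], []
    fits = {}
    for g in manifest.get("kinetics", {}).get("groups", []):
        cond = _conditions_from_entry(g)
        traces = []
        for f in g["files"]:
            wells = read_well_csv(base_dir / f)
            nt = normalize_trace(wells["reaction"], wells["pre_activated"],
                                 wells["negative"], conditions=cond)
            traces.append((f, nt))
        method = g.get("fit", "auto")
        per = []
        for f, nt in traces:
            from .kinetics import _fit_with_method
            try:
                res = _fit_with_method(nt, cond, method, **fit_kwargs)
            except ValueError as exc:
                res = None
                rows.append({"group": g["label"], "replicate": f, "k_per_M_s": np.nan,
                             "method": method, "r_squared": np.nan, "n_points": 0,
                             "success": False, "deviation_flag": False,
                             "error": str(exc)})
            if res is not None:
                per.append(res)
                rows.append({"group": g["label"], "replicate": f, "k_per_M_s": res.k,
                             "method": res.method, "r_squared": res.r_squared,
                             "n_points": res.n_points_used, "success": res.success,
                             "deviation_flag": res.deviation_flag, "error": ""})
        ks = [r.k for r in per if r.success]
        group_fit = fit_replicates([nt for _, nt in traces], cond, method=method,
                                   label=g["label"], **fit_kwargs)
        fits[g["label"]] = group_fit
        summary_rows.append({
            "group": g["label"], "n_replicates": len(traces),
            "n_successful": len(ks), "k_mean_per_M_s": group_fit.replicate_mean,
            "k_sd_per_M_s": group_fit.replicate_sd if group_fit.replicate_sd is not None else np.nan,
            "method": group_fit.method, "r_squared": group_fit.r_squared,
            "toehold_length": g.get("toehold_length", np.nan),
            "chemistry": g.get("chemistry", ""),
            "configuration": g.get("configuration", ""),
            "mismatch": g.get("mismatch", "") or "",
        })

    tables = {
        "rates": pd.DataFrame(rows),
        "rate_summary": pd.DataFrame(summary_rows),
    }

    derived = manifest.get("kinetics", {}).get("derived", {})
    df_rows = []
    for d in derived.get("discrimination", []):
        row = {"label": d.get("label", f"{d['match']}/{d['mismatch']}"),
               "match": d["match"], "mismatch": d["mismatch"]}
        try:
            res = discrimination_factor(fits[d["match"]], fits[d["mismatch"]])
            row.update({"df": res.df, "df_sd": res.df_sd if res.df_sd is not None else np.nan,
                        "is_bound": res.is_bound, "display": str(res), "error": ""})
        except ValueError as exc:
            row.update({"df": np.nan, "df_sd": np.nan, "is_bound": False,
                        "display": "", "error": str(exc)})
        df_rows.append(row)
    if df_rows:
        tables["discrimination"] = pd.DataFrame(df_rows)

    ratio_rows = []
    for d in derived.get("ratios", []):
        row = {"label": d.get("label", f"{d['numerator']}/{d['denominator']}"),
               "numerator": d["numerator"], "denominator": d["denominator"]}
        try:
            res = rate_ratio(fits[d["numerator"]], fits[d["denominator"]])
            row.update({"ratio": res.ratio,
                        "ratio_sd": res.ratio_sd if res.ratio_sd is not None else np.nan,
                        "is_bound": res.is_bound, "error": ""})
        except ValueError as exc:
            row.update({"ratio": np.nan, "ratio_sd": np.nan, "is_bound": False,
                        "error": str(exc)})
        ratio_rows.append(row)
    if ratio_rows:
        tables["ratios"] = pd.DataFrame(ratio_rows)

    toehold_rows = []
    group_meta = {g["label"]: g for g in manifest.get("kinetics", {}).get("groups", [])}
    for d in derived.get("toehold_regression", []):
        row = {"label": d.get("label", "toehold")}
        try:
            members = [g for g in d["groups"] if fits[g].success]
            lengths = [group_meta[g]["toehold_length"] for g in members]
            ks = [fits[g].replicate_mean for g in members]
            series = fit_toehold_dependence(lengths, ks)
            row.update({"slope_per_nt": series.slope, "intercept": series.intercept,
                        "fold_per_nt": series.fold_per_nt,
                        "r_squared": series.r_squared, "n_lengths": len(lengths),
                        "error": ""})
        except (ValueError, KeyError) as exc:
            row.update({"slope_per_nt": np.nan, "intercept": np.nan,
                        "fold_per_nt": np.nan, "r_squared": np.nan, "n_lengths": 0,
                        "error": str(exc)})
        toehold_rows.append(row)
    if toehold_rows:
        tables["toehold"] = pd.DataFrame(toehold_rows)

    return AnalysisReport(tables=tables, provenance=_provenance(manifest, config))


def run_melt(manifest: dict, base_dir, config: dict | None = None) -> AnalysisReport:
    """Correct, extract Tm and run the van't Hoff regression for each melt set.

    Tm rows are emitted even when the van't Hoff stage fails (e.g. fewer
    than three concentrations); the failure is recorded in the thermo
    table's ``error`` column.
    """
    base_dir = Path(base_dir)
    validate_manifest(manifest, base_dir)
    config = config or {}
    smooth = bool(config.get("tm_smooth", True))

    tm_rows, thermo_rows = [], []
    for s in manifest.get("melt", {}).get("sets", []):
        tms = []
        for e in s["files"]:
            ct = um_to_molar(float(e["ct_uM"]))
            row = {"set": s["label"], "file": e["file"], "ct_uM": float(e["ct_uM"])}
            try:
                curve = read_melt_csv(base_dir / e["file"], ct=ct)
                profile = correct_melt(curve)
                tm = estimate_tm(profile, smooth=smooth)
                tms.append(tm)
                row.update({"tm_C": tm.tm, "error": ""})
            except ValueError as exc:
                row.update({"tm_C": np.nan, "error": str(exc)})
            tm_rows.append(row)
        row = {"set": s["label"], "n_concentrations": len({t.ct for t in tms})}
        try:
            fit = fit_vant_hoff(tms, n=int(s.get("n", 2)),
                                t_ref=float(s.get("t_ref_K", 310.15)))
            row.update({"dH_kcal_mol": fit.dH, "dS_kcal_mol_K": fit.dS,
                        "dG_ref_kcal_mol": fit.dG_at, "t_ref_K": fit.t_ref,
                        "dH_sd": fit.dH_sd, "dS_sd": fit.dS_sd,
                        "r_squared": fit.r_squared, "error": ""})
        except ValueError as exc:
            row.update({"dH_kcal_mol": np.nan, "dS_kcal_mol_K": np.nan,
                        "dG_ref_kcal_mol": np.nan, "t_ref_K": np.nan,
                        "dH_sd": np.nan, "dS_sd": np.nan, "r_squared": np.nan,
                        "error": str(exc)})
        thermo_rows.append(row)

    tables = {"tm": pd.DataFrame(tm_rows), "thermo": pd.DataFrame(thermo_rows)}
    return AnalysisReport(tables=tables, provenance=_provenance(manifest, config))


def run_all(manifest_path, out_dir=None, config: dict | None = None) -> AnalysisReport:
    """Run every stage the manifest requests; optionally write the report."""
    manifest_path = Path(manifest_path)
    manifest = load_yaml(manifest_path)
    base_dir = manifest_path.parent
    tables, prov = {}, None
    if "kinetics" in manifest:
        rep = run_kinetics(manifest, base_dir, config)
        tables.update(rep.tables)
        prov = rep.provenance
    if "melt" in manifest:
        rep = run_melt(manifest, base_dir, config)
        tables.update(rep.tables)
        prov = rep.provenance
    if prov is None:
        validate_manifest(manifest, base_dir)  # raises with details
    report = AnalysisReport(tables=tables, provenance=prov)
    if out_dir is not None:
        report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# Fixture scenarios


def observation_window(k: float, in0: float, n_points: int = 400,
                       min_duration: float = 600.0, max_duration: float = 1e4):
    """Observation window sized to the reaction: ~20 pseudo-first-order
    timescales, clamped to [min_duration, max_duration]; returns
    (duration, sampling_interval) in seconds."""
    duration = min(max(20.0 / (k * in0), min_duration), max_duration)
    return duration, duration / n_points


def _regime_conditions(name: str) -> dict:
    return {
        "A": {"in0_nM": 150.0, "ai0_nM": 100.0, "r0_nM": 300.0, "temperature_C": 37.0},
        "B": {"in0_nM": 30.0, "ai0_nM": 20.0, "r0_nM": 60.0, "temperature_C": 37.0},
    }[name]


def _write_kinetics_group(out_dir: Path, label: str, k: float, cond_nm: dict,
                          n_replicates: int, noise_sd: float, seed_seq) -> list:
    cond = ReactionConditions(
        in0=nm_to_molar(cond_nm["in0_nM"]), ai0=nm_to_molar(cond_nm["ai0_nM"]),
        r0=nm_to_molar(cond_nm["r0_nM"]), temperature=cond_nm.get("temperature_C", 37.0))
    duration, dt = observation_window(k, cond.in0)
    files = []
    for rep, child in enumerate(seed_seq.spawn(n_replicates), start=1):
        # Reporter step kept >= 1000x faster than displacement so the
        # single-step fitting assumption holds for the fixtures.
        spec = TraceSimulationSpec(
            k_displacement=k, k_reporter=max(1e3 * k, 1e6), conditions=cond,
            duration=duration, sampling_interval=dt, noise_sd=noise_sd,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        wells = simulate_displacement_wells(spec)
        fname = f"{label}_rep{rep}.csv"
        write_well_csv(out_dir / fname, wells)
        files.append(fname)
    return files


def _scenario_toehold_ladder(out_dir: Path, seed: int, noise_sd: float = 0.01):
    """Toehold ladder 0-10 nt with log10 k linear in length (slope 0.35)."""
    root = np.random.SeedSequence(seed)
    lengths = list(range(11))
    slope, intercept = 0.35, 1.5
    groups, truth = [], {"slope": slope, "intercept": intercept, "k_by_length": {}}
    for length, child in zip(lengths, root.spawn(len(lengths))):
        k = 10.0 ** (intercept + slope * length)
        label = f"TH_{length}"
        files = _write_kinetics_group(out_dir, label, k, _regime_conditions("A"),
                                      3, noise_sd, child)
        groups.append({"label": label, "toehold_length": length, "chemistry": "DNA",
                       "configuration": "hetero", "mismatch": None,
                       "conditions": _regime_conditions("A"), "files": files})
        truth["k_by_length"][length] = k
    derived = {"toehold_regression": [
        {"label": "ladder_2_10", "groups": [f"TH_{L}" for L in (2, 4, 6, 8, 10)]},
        {"label": "ladder_full", "groups": [f"TH_{L}" for L in lengths]},
    ]}
    manifest = {"schema_version": 1, "seed": seed,
                "kinetics": {"groups": groups, "derived": derived}}
    return manifest, truth


#: Mismatch discrimination ground truths used as generator settings: the
#: reported matched/mismatched rate ratios for a toehold mismatch in
#: both chiral configurations (5.8 homo / 29.4 hetero), a double toehold
#: mismatch (20.8 homo / 36.1 hetero), and one unresolvably slow
#: mismatch encoded far below the resolvability floor (reported
#: downstream as a bound, "DF > X").
MISMATCH_DF_TRUTH = {"MM_A_homo": 5.8, "MM_A_hetero": 29.4,
                     "MM_B_homo": 20.8, "MM_B_hetero": 36.1}


def _scenario_mismatch_panel(out_dir: Path, seed: int, noise_sd: float = 0.01):
    root = np.random.SeedSequence(seed)
    k_match = {"homo": 2e5, "hetero": 2e4}
    groups, derived_df, truth = [], [], {"df": dict(MISMATCH_DF_TRUTH)}
    children = iter(root.spawn(2 * (1 + 2) + 1))
    for config in ("homo", "hetero"):
        label = f"match_{config}"
        files = _write_kinetics_group(out_dir, label, k_match[config],
                                      _regime_conditions("A"), 3, noise_sd, next(children))
        groups.append({"label": label, "toehold_length": 8, "chemistry": "DNA",
                       "configuration": config, "mismatch": None,
                       "conditions": _regime_conditions("A"), "files": files})
        for mm in ("MM_A", "MM_B"):
            df_true = MISMATCH_DF_TRUTH[f"{mm}_{config}"]
            label_mm = f"{mm}_{config}"
            files = _write_kinetics_group(out_dir, label_mm, k_match[config] / df_true,
                                          _regime_conditions("A"), 3, noise_sd,
                                          next(children))
            groups.append({"label": label_mm, "toehold_length": 8, "chemistry": "DNA",
                           "configuration": config, "mismatch": mm,
                           "conditions": _regime_conditions("A"), "files": files})
            derived_df.append({"label": label_mm, "match": label, "mismatch": label_mm})
    # An unresolvable mismatch: k far below the resolvability floor.
    files = _write_kinetics_group(out_dir, "MM_C_hetero", 1.0,
                                  _regime_conditions("A"), 3, noise_sd, next(children))
    groups.append({"label": "MM_C_hetero", "toehold_length": 8, "chemistry": "DNA",
                   "configuration": "hetero", "mismatch": "MM_C",
                   "conditions": _regime_conditions("A"), "files": files})
    derived_df.append({"label": "MM_C_hetero", "match": "match_hetero",
                       "mismatch": "MM_C_hetero"})
    truth["k_match"] = k_match
    truth["unresolvable"] = {"MM_C_hetero": 1.0}
    manifest = {"schema_version": 1, "seed": seed,
                "kinetics": {"groups": groups,
                             "derived": {"discrimination": derived_df}}}
    return manifest, truth


#: Incumbent-toehold slowdown factors k(L)/k(0) used as generator
#: settings; the 8-nt incumbent toehold slows the homochiral reaction
#: ~30-fold but the heterochiral one only ~2.5-fold.
INCUMBENT_FACTORS = {
    "homo": {0: 1.0, 4: 0.9, 6: 0.33, 8: 1.0 / 30.0},
    "hetero": {0: 1.0, 4: 0.95, 6: 0.6, 8: 1.0 / 2.5},
}


def _scenario_incumbent_toehold(out_dir: Path, seed: int, noise_sd: float = 0.01):
    root = np.random.SeedSequence(seed)
    k0 = {"homo": 2e5, "hetero": 2e4}
    groups, ratios, truth = [], [], {"factors": INCUMBENT_FACTORS, "k0": k0}
    children = iter(root.spawn(8))
    for config in ("homo", "hetero"):
        for length, factor in INCUMBENT_FACTORS[config].items():
            label = f"inc{length}_{config}"
            files = _write_kinetics_group(out_dir, label, k0[config] * factor,
                                          _regime_conditions("B"), 3, noise_sd,
                                          next(children))
            groups.append({"label": label, "toehold_length": 8, "chemistry": "DNA",
                           "configuration": config, "incumbent_toehold": length,
                           "mismatch": None, "conditions": _regime_conditions("B"),
                           "files": files})
            if length != 0:
                ratios.append({"label": f"slowdown_inc{length}_{config}",
                               "numerator": f"inc0_{config}", "denominator": label})
    manifest = {"schema_version": 1, "seed": seed,
                "kinetics": {"groups": groups, "derived": {"ratios": ratios}}}
    return manifest, truth


#: RNA-vs-DNA input acceleration factors k_RNA/k_DNA per toehold length.
RNA_FACTORS = {6: 20.0, 8: 8.0, 10: 4.0}


def _scenario_rna_vs_dna(out_dir: Path, seed: int, noise_sd: float = 0.01):
    root = np.random.SeedSequence(seed)
    groups, ratios, truth = [], [], {"rna_factors": RNA_FACTORS, "k_dna": {}}
    children = iter(root.spawn(6))
    for length in (6, 8, 10):
        k_dna = 10.0 ** (1.5 + 0.35 * length)
        truth["k_dna"][length] = k_dna
        for chem, k in (("DNA", k_dna), ("RNA", k_dna * RNA_FACTORS[length])):
            label = f"{chem}_{length}"
            files = _write_kinetics_group(out_dir, label, k, _regime_conditions("B"),
                                          3, noise_sd, next(children))
            groups.append({"label": label, "toehold_length": length, "chemistry": chem,
                           "configuration": "hetero", "mismatch": None,
                           "conditions": _regime_conditions("B"), "files": files})
        ratios.append({"label": f"rna_over_dna_{length}",
                       "numerator": f"RNA_{length}", "denominator": f"DNA_{length}"})
    manifest = {"schema_version": 1, "seed": seed,
                "kinetics": {"groups": groups, "derived": {"ratios": ratios}}}
    return manifest, truth


#: Synthetic association thermodynamics (kcal units) for a stronger
#: (homochiral-like) and weaker (heterochiral-like) toehold; chosen to
#: reproduce a low-tens-of-degrees Tm separation at Ct = 2 uM.
MELT_PARAM_SETS = {
    "strong": {"dH": -65.0, "dS": -0.175},
    "weak": {"dH": -57.0, "dS": -0.1565},
}


def _scenario_melt_ladder(out_dir: Path, seed: int, noise_sd: float = 0.01):
    root = np.random.SeedSequence(seed)
    sets, truth = [], {"params": MELT_PARAM_SETS}
    for (name, params), child in zip(MELT_PARAM_SETS.items(), root.spawn(2)):
        spec = MeltSimulationSpec(
            dH=params["dH"], dS=params["dS"], noise_sd=noise_sd,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        curves = simulate_melt_wells(spec)
        entries = []
        for ct, curve in curves.items():
            ct_um = ct / 1e-6
            fname = f"melt_{name}_{ct_um:g}uM.csv"
            write_melt_csv(out_dir / fname, curve)
            entries.append({"file": fname, "ct_uM": float(f"{ct_um:g}")})
        sets.append({"label": name, "n": 2, "t_ref_K": 310.15, "files": entries})
    manifest = {"schema_version": 1, "seed": seed, "melt": {"sets": sets}}
    return manifest, truth


SCENARIOS = {
    "toehold_ladder": _scenario_toehold_ladder,
    "mismatch_panel": _scenario_mismatch_panel,
    "incumbent_toehold": _scenario_incumbent_toehold,
    "rna_vs_dna": _scenario_rna_vs_dna,
    "melt_ladder": _scenario_melt_ladder,
}


def make_fixtures(scenario: str, seed: int, out_dir, noise_sd: float = 0.01) -> Path:
    """Write a complete, immediately analyzable synthetic dataset.

    Produces the data CSVs, a ``manifest.yaml`` and a ``truth.yaml``
    sidecar holding the generator's ground-truth parameters and seed.
    Returns the manifest path.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, truth = SCENARIOS[scenario](out_dir, seed, noise_sd=noise_sd)
    save_yaml(out_dir / "manifest.yaml", manifest)
    save_yaml(out_dir / "truth.yaml",
              {"scenario": scenario, "seed": seed, "noise_sd": noise_sd, "truth": truth})
    return out_dir / "manifest.yaml"
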