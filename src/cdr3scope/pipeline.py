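"""End-to-end orchestration: repertoire branch and structure branch.

Every number emitted here traces to an operation in the feature/stats
modules; this layer only sequences them, groups/stratifies, and writes
tables plus a machine-readable run manifest.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .regions import RegionSpec, default_region_spec
from .repertoire import Repertoire, filter_repertoire, length_summary, parse_repertoire
from .seqfeatures import AA_CLASS_NAMES, FEATURE_BLOCKS, region_feature_table
from .stats import correlation_report, f_variance_ratio, mann_whitney_u, stars
from .structfeatures import (
    buried_surface_area,
    classify_conformation,
    contact_residues,
    fr2_cdr3_dis,
    interface_summary,
    segment_interaction_profile,
    shrake_rupley_sasa,
    ss_usage,
    surface_hydrophobicity,
)
from .structure_io import SS_CODES, ComplexModel, load_complex, parse_dssp
from .usage import germline_length_preference, positional_usage_vs_length, regional_usage_vs_length

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "cdr3scope_out"
    min_count: int = 5
    z_max: float = 2.5
    fdr_level: float = 0.05
    positional_min_n: int = 100
    contact_threshold: float = 4.0
    min_epitope: int = 6
    min_stratum: int = 10
    sasa_points: int = 240  # per-atom sample points at dataset scale
    usage_regions: tuple[str, ...] = ("CDR1", "FR2", "CDR3")
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _write_manifest(out_dir: Path, cfg: RunConfig, counts: dict, branch: str) -> None:
    manifest = {
        "tool": "cdr3scope",
        "version": __version__,
        "branch": branch,
        "config": asdict(cfg),
        "counts": counts,
    }
    (out_dir / f"manifest_{branch}.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_repertoire_branch(
    repertoires: dict[str, "Repertoire | str | Path"],
    cfg: RunConfig | None = None,
    spec: dict[str, RegionSpec] | None = None,
) -> dict:
    """Filter, extract features, run usage and germline screens per species
    group, and compare CDR3 length distributions across groups.

    ``repertoires`` maps a group label (e.g. species) to a Repertoire or a
    repertoire TSV path.  Returns the report bundle as a dict of DataFrames
    (all also written to ``cfg.out_dir``).
    """
    cfg = cfg or RunConfig()
    spec = spec or default_region_spec()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    filtered: dict[str, Repertoire] = {}
    counts: dict = {}
    for label, rep in sorted(repertoires.items()):
        if not isinstance(rep, Repertoire):
            rep = parse_repertoire(rep, species=label if label in
                                   ("alpaca", "llama", "bactrian", "human") else "other")
        if not rep.members:
            raise ValueError(f"group {label!r}: empty input repertoire")
        filt = filter_repertoire(rep, cfg.min_count, cfg.z_max)
        filtered[label] = filt
        counts[label] = [
            {"filter": s.name, "n_before": s.n_before, "n_after": s.n_after}
            for s in filt.filters_applied
        ]

    bundle: dict = {"filtered": filtered}

    # per-group feature correlations and usage screens
    feature_frames, regional_frames, positional_frames = [], [], []
    germline_summaries, germline_tests = [], []
    summary_rows = []
    for label, rep in filtered.items():
        summary_rows.append({"group": label, **length_summary(rep)})
        feats = region_feature_table(rep, spec)
        feature_cols = [f"{b}_{f}" for b in FEATURE_BLOCKS for f in ("charge", "hydropathy")]
        rpt = correlation_report(feats, "cdr3_length", feature_cols, group=label, fdr_level=cfg.fdr_level)
        feature_frames.append(rpt)
        for region in cfg.usage_regions:
            reg = regional_usage_vs_length(rep, region, spec, cfg.fdr_level)
            reg.insert(0, "group", label)
            regional_frames.append(reg)
            posu = positional_usage_vs_length(rep, region, spec, cfg.positional_min_n, cfg.fdr_level)
            posu.insert(0, "group", label)
            positional_frames.append(posu)
        if any(m.germline for m in rep.members):
            summary, pairwise = germline_length_preference(rep, spec, cfg.fdr_level)
            summary.insert(0, "group", label)
            pairwise.insert(0, "group", label)
            germline_summaries.append(summary)
            germline_tests.append(pairwise)

    bundle["length_summary"] = pd.DataFrame(summary_rows)
    bundle["feature_correlations"] = pd.concat(feature_frames, ignore_index=True)
    bundle["regional_usage"] = pd.concat(regional_frames, ignore_index=True)
    bundle["positional_usage"] = pd.concat(positional_frames, ignore_index=True)
    if germline_summaries:
        bundle["germline_summary"] = pd.concat(germline_summaries, ignore_index=True)
        bundle["germline_tests"] = pd.concat(germline_tests, ignore_index=True)

    # cross-group CDR3 length comparison: Mann-Whitney + variance-ratio F
    rows = []
    for a, b in itertools.combinations(sorted(filtered), 2):
        la = filtered[a].cdr3_lengths(spec)
        lb = filtered[b].cdr3_lengths(spec)
        sa, sb = bundle["length_summary"].set_index("group").loc[[a, b], "std"]
        u, p_u = mann_whitney_u(la, lb)
        F, p_f = f_variance_ratio(sa, len(la), sb, len(lb))
        rows.append({
            "group_a": a, "group_b": b,
            "mean_diff": float(np.mean(la) - np.mean(lb)),
            "mannwhitney_U": u, "mannwhitney_p": p_u, "mannwhitney_stars": stars(p_u),
            "F": F, "F_p": p_f,
        })
    bundle["length_comparison"] = pd.DataFrame(rows)

    for name in ("length_summary", "feature_correlations", "regional_usage",
                 "positional_usage", "germline_summary", "germline_tests", "length_comparison"):
        if name in bundle:
            bundle[name].to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    _write_manifest(out_dir, cfg, counts, "repertoire")
    return bundle


# -- structure branch ----------------------------------------------------

def load_structure_dir(
    directory: str | Path,
    chainmap: "str | Path | dict | None" = None,
    dssp_dir: str | Path | None = None,
) -> list[ComplexModel]:
    """Load every ``*.pdb`` in a directory, attaching DSSP labels when a
    matching ``*.dssp`` file exists.  Failing structures are logged and
    skipped; the load fails only if nothing loads."""
    directory = Path(directory)
    chainmap = chainmap or directory / "chainmap.json"
    dssp_dir = Path(dssp_dir) if dssp_dir else directory
    models = []
    for pdb in sorted(directory.glob("*.pdb")):
        try:
            m = load_complex(pdb, chainmap)
        except (ValueError, OSError) as exc:
            logger.warning("skipping %s: %s", pdb.name, exc)
            continue
        dssp = dssp_dir / f"{pdb.stem}.dssp"
        if dssp.exists():
            m.ss_labels = parse_dssp(dssp)
        models.append(m)
    if not models:
        raise ValueError(f"no structure in {directory} could be loaded")
    return models


def structure_feature_table(
    models: list[ComplexModel],
    cfg: RunConfig | None = None,
    with_sasa: bool = True,
) -> pd.DataFrame:
    """Per-structure feature rows: CDR3 geometry, intra-domain contact
    profile, interface bookkeeping, SASA-derived scores, SS fractions."""
    cfg = cfg or RunConfig()
    rows = []
    for m in models:
        intra = contact_residues(m, cfg.contact_threshold, mode="intra_vhh")
        profile = segment_interaction_profile(m, contacts=intra)
        iface = interface_summary(m, cfg.contact_threshold, cfg.min_epitope)
        row: dict = {
            "id": m.name,
            "cdr3_length": len(m.cdr3_residues()),
            "fr2_cdr3_dis": fr2_cdr3_dis(m),
            "rejected": iface.rejected,
            "fr2_involved": iface.fr2_involved,
            "epitope_size": len(iface.epitope),
            "paratope_size": len(iface.paratope),
            "vhh_sequence": m.vhh_sequence(),
        }
        for seg, n in profile.items():
            row[f"contacts_CDR3_{seg}"] = n
        for seg, n in iface.paratope_counts.items():
            row[f"paratope_{seg}"] = n
        for cls in AA_CLASS_NAMES:
            row[f"paratope_{cls}"] = iface.paratope_classes[cls]
            row[f"epitope_{cls}"] = iface.epitope_classes[cls]
        if with_sasa:
            sasa_vhh = shrake_rupley_sasa(m, n_points=cfg.sasa_points, atoms=m.vhh_atoms())
            row["sasa_vhh"] = sum(sasa_vhh.values())
            row["surface_hydrophobicity"] = surface_hydrophobicity(m, sasa=sasa_vhh)
            row.update(buried_surface_area(m, n_points=cfg.sasa_points))
        ss = ss_usage(m, "CDR3")
        if ss is not None:
            for code in SS_CODES:
                row[f"ss_{code}"] = ss[code]
        rows.append(row)
    return pd.DataFrame(rows)


STRUCT_FEATURES_CORE = (
    "fr2_cdr3_dis", "paratope_size", "epitope_size",
    "paratope_CDR3", "paratope_FR2", "paratope_CDR1", "paratope_CDR2",
    "contacts_CDR3_FR1", "contacts_CDR3_CDR1", "contacts_CDR3_FR2",
    "contacts_CDR3_CDR2", "contacts_CDR3_CDR3_internal",
)


def run_structure_branch(
    models: "list[ComplexModel] | str | Path",
    cfg: RunConfig | None = None,
    with_sasa: bool = True,
) -> dict:
    """Structure-branch pipeline: feature extraction, epitope-size filter,
    sequence-redundancy removal, conformation classification, and
    CDR3-length correlations overall and within
    {bent, extended} x {FR2-involved, FR2-uninvolved} strata."""
    cfg = cfg or RunConfig()
    if not isinstance(models, list):
        models = load_structure_dir(models)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = structure_feature_table(models, cfg, with_sasa=with_sasa)
    counts = {"loaded": len(table)}
    table = table[~table["rejected"]].copy()
    counts["epitope_filter"] = len(table)
    table = table.drop_duplicates(subset="vhh_sequence", keep="first")
    counts["redundancy_filter"] = len(table)

    conf = classify_conformation(table["fr2_cdr3_dis"].to_numpy())
    table["conformation"] = conf.labels
    counts["bent"] = int(sum(c == "bent" for c in conf.labels))
    counts["extended"] = int(sum(c == "extended" for c in conf.labels))

    feature_cols = [c for c in STRUCT_FEATURES_CORE if c in table.columns]
    feature_cols += [c for c in table.columns if c.startswith("ss_")]
    feature_cols += [f"paratope_{c}" for c in AA_CLASS_NAMES] + [f"epitope_{c}" for c in AA_CLASS_NAMES]
    if with_sasa:
        feature_cols += ["sasa_vhh", "surface_hydrophobicity", "interface_bsa",
                         "paratope_bsa", "epitope_bsa"]
    feature_cols = list(dict.fromkeys(feature_cols))

    reports = [correlation_report(table, "cdr3_length", feature_cols, group="all",
                                  fdr_level=cfg.fdr_level)]
    strata = [("conformation", v) for v in ("bent", "extended")]
    strata += [("fr2_involved", v) for v in (True, False)]
    for col, value in strata:
        sub = table[table[col] == value]
        label = f"{col}={value}"
        if len(sub) < cfg.min_stratum:
            logger.warning("stratum %s has n=%d < %d; correlations suppressed",
                           label, len(sub), cfg.min_stratum)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(correlation_report(sub, "cdr3_length", feature_cols,
                                              group=label, fdr_level=cfg.fdr_level))

    bundle = {
        "features": table,
        "conformation_threshold": conf.threshold,
        "correlations": pd.concat(reports, ignore_index=True),
        "counts": counts,
    }
    table.to_csv(out_dir / "structure_features.tsv", sep="\t", index=False)
    bundle["correlations"].to_csv(out_dir / "structure_correlations.tsv", sep="\t", index=False)
    _write_manifest(out_dir, cfg, counts, "structure")
    return bundle
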