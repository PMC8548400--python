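"""End-to-end orchestration: config in, deterministic TSV outputs out.

A single YAML/dict config drives the full analysis: obtain a peptide table
(from a file or from the digestion simulator), map it onto the substrate,
apply the replicate filter, then derive site usage and preference, the
occupancy heatmap with MDS/Ward ordination, length summaries and tests,
cleavage-site composition logos, product diversity, remnant annotations,
and (optionally) disorder comparisons.  A run manifest — config snapshot,
input digests, seeds, package version, per-stage row counts — is written
before any result so every output can reference it; re-running with the
same manifest inputs reproduces the numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io
from .core_io import (
    AnalysisConfig,
    PeptideTable,
    SubstrateRecord,
    ValidationError,
    load_peptides,
    load_substrate,
    write_table,
    logger,
)
from .cleavage_analysis import (
    build_heatmap,
    compute_preference,
    diversity,
    integrate_site_counts,
    linkage_to_newick,
    mds_ward_cluster,
)
from .cleavage_composition import (
    differential_logo,
    extract_windows,
    frequency_matrix,
    information_content,
)
from .digestion_simulator import DigestionModel, simulate_condition
from .peptide_mapping import filter_replicates, map_table
from .peptidome_metrics import (
    mann_whitney_u,
    mean_disorder,
    peptide_lengths,
    summarize_lengths,
    unique_condition_proteins,
    welch_t,
)
from .remnant_annotation import annotate_branched_peptide, enumerate_remnants

FIXTURES = {
    "cyclin_b1_nt": core_io.cyclin_b1_nt,
    "cyclin_b1_nt_k64": core_io.cyclin_b1_nt_k64,
    "ubiquitin": core_io.ubiquitin,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_substrate(spec: dict) -> SubstrateRecord:
    if "fixture" in spec:
        return FIXTURES[spec["fixture"]]()
    return load_substrate(
        spec["fasta"],
        name=spec.get("name"),
        segments=[tuple(s) for s in spec.get("segments", [])],
        anchor_lysines=spec.get("anchor_lysines", []),
    )


def _obtain_table(config: dict, substrate: SubstrateRecord, seed: int) -> PeptideTable:
    if "peptides" in config:
        spec = config["peptides"]
        return load_peptides(spec["path"], dialect=spec.get("dialect", "generic"))
    sim = config["simulate"]
    frames = []
    rng = np.random.default_rng(seed)
    for i, (condition, params) in enumerate(sorted(sim["conditions"].items())):
        params = dict(params)
        weights = params.pop("site_weights", None)
        if weights is None:
            weights = np.ones(len(substrate) - 1)
        model = DigestionModel(
            substrate_id=substrate.id,
            site_weights=np.asarray(weights, float),
            seed=params.pop("seed", int(rng.integers(0, 2**31 - 100))),
            **params,
        )
        frames.append(simulate_condition(model, substrate, condition))
    frame = pd.concat(frames, ignore_index=True)
    return PeptideTable(frame[core_io.PEPTIDE_COLUMNS], provenance="simulated")


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir``; returns the output directory.

    Stage failures raise :class:`StageError` labelled with the stage name.
    The disorder stage is optional: absent inputs produce a warning, not a
    failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = AnalysisConfig(**config.get("analysis", {}))
    seed = int(config.get("seed", analysis.seed))
    counts: dict[str, int] = {}

    manifest_path = out / "manifest.yaml"
    manifest = {
        "package": "degradomics",
        "version": importlib.metadata.version("degradomics"),
        "seed": seed,
        "config": config,
        "analysis": dict(analysis.as_header_items()),
        "input_digests": {
            str(p): _digest_file(Path(p))
            for p in _input_paths(config)
            if Path(p).exists()
        },
    }
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    header = {"manifest": manifest_path.name}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrap

    substrate = stage("substrate")(lambda: _resolve_substrate(config["substrate"]))
    table = stage("ingest")(lambda: _obtain_table(config, substrate, seed))
    counts["ingest_rows"] = len(table)

    mapped, unmapped = stage("map")(
        lambda: map_table(table, substrate, analysis.il_equivalence)
    )
    counts["mapped_rows"], counts["unmapped_rows"] = len(mapped), len(unmapped)
    write_table(mapped, out / "mapped_peptides.tsv", analysis, header)
    if len(unmapped):
        write_table(unmapped, out / "unmapped_peptides.tsv", analysis, header)

    filtered = stage("filter")(
        lambda: filter_replicates(table, analysis.min_replicates)
    )
    counts["filtered_rows"] = len(filtered)
    fmapped, _ = map_table(filtered, substrate, analysis.il_equivalence)

    conditions = config.get("conditions") or sorted(
        filtered.frame["condition"].unique()
    )

    def _p1():
        usages = {
            c: integrate_site_counts(fmapped, c) for c in conditions
        }
        usage_frames = []
        for c, u in usages.items():
            usage_frames.append(
                pd.DataFrame(
                    {"site": u.counts.index, "condition": c, "count": u.counts.values}
                )
            )
        write_table(
            pd.concat(usage_frames, ignore_index=True)
            if usage_frames
            else pd.DataFrame(columns=["site", "condition", "count"]),
            out / "site_usage.tsv", analysis, header,
        )
        if len(conditions) >= 2:
            pref = compute_preference(
                usages[conditions[0]],
                usages[conditions[1]],
                pseudo_value=analysis.pseudo_value,
                fold_threshold=analysis.fold_threshold,
                substrate_length=len(substrate),
                normalize_cpm=analysis.preference_normalization == "cpm",
            )
            write_table(pref, out / "preference.tsv", analysis, header)
            counts["preference_sites"] = int(pref["log2_ratio"].notna().sum())
        return usages

    usages = stage("p1")(_p1)

    def _heatmap():
        hm = build_heatmap(filtered, fmapped, analysis.min_sample_psms)
        values = hm.values.copy()
        values.insert(0, "sample_id", values.index)
        write_table(values, out / "heatmap.tsv", analysis, header)
        write_table(
            hm.peptide_maxima.rename("max_cpm").rename_axis("sequence").reset_index(),
            out / "peptide_maxima.tsv", analysis, header,
        )
        if hm.values.shape[0] >= 2:
            coords, z = mds_ward_cluster(hm, analysis.top_n_peptides)
            write_table(
                coords.rename_axis("sample_id").reset_index(),
                out / "mds_coordinates.tsv", analysis, header,
            )
            (out / "dendrogram.nwk").write_text(
                linkage_to_newick(z, list(coords.index)) + "\n"
            )
        return hm

    stage("heatmap")(_heatmap)

    def _lengths():
        rows = [summarize_lengths(filtered, c).__dict__ for c in conditions]
        write_table(pd.DataFrame(rows), out / "length_summary.tsv", analysis, header)
        if len(conditions) >= 2:
            x = peptide_lengths(filtered, conditions[0])
            y = peptide_lengths(filtered, conditions[1])
            u, p = mann_whitney_u(x, y)
            write_table(
                pd.DataFrame(
                    [{"test": "mann_whitney_u", "a": conditions[0],
                      "b": conditions[1], "U": u, "p_value": p}]
                ),
                out / "length_test.tsv", analysis, header,
            )

    stage("lengths")(_lengths)

    def _composition():
        span = int(config.get("composition", {}).get("span", 4))
        mats = {}
        for c in conditions:
            if usages[c].counts.empty:
                continue
            windows = extract_windows(usages[c], substrate, span)
            freqs = frequency_matrix(windows, span)
            mats[c] = freqs
            logo = information_content(freqs)
            write_table(
                freqs.frequencies.rename_axis("position").reset_index(),
                out / f"composition_{c}.tsv", analysis, header,
            )
            write_table(
                logo.heights.rename_axis("position").reset_index(),
                out / f"logo_{c}.tsv", analysis, header,
            )
        if len(conditions) >= 2 and all(c in mats for c in conditions[:2]):
            diff, pvals = differential_logo(mats[conditions[0]], mats[conditions[1]])
            diff = diff.rename_axis("position").reset_index()
            diff["p_value"] = pvals.values
            write_table(diff, out / "composition_differential.tsv", analysis, header)

    stage("composition")(_composition)

    def _diversity():
        rows = [diversity(filtered, c).__dict__ for c in conditions]
        write_table(pd.DataFrame(rows), out / "diversity.tsv", analysis, header)

    stage("diversity")(_diversity)

    def _remnants():
        spec = config.get("remnants", {})
        ub = FIXTURES["ubiquitin"]()
        remnants = enumerate_remnants(
            ub, spec.get("min_len", 2), spec.get("max_len", 4)
        )
        write_table(
            pd.DataFrame(
                [
                    {"sequence": r.sequence, "paper_notation": r.paper_notation,
                     "length": r.length, "mono_mass": r.mono_mass}
                    for r in remnants
                ]
            ),
            out / "remnants.tsv", analysis, header,
        )
        branched = [
            o for o in filtered.observations if o.branch is not None
        ]
        if branched:
            annotations = [
                annotate_branched_peptide(o, substrate, ub).__dict__
                for o in branched
            ]
            write_table(
                pd.DataFrame(annotations), out / "branched_annotations.tsv",
                analysis, header,
            )
            counts["branched_observations"] = len(branched)

    stage("remnants")(_remnants)

    def _disorder():
        spec = config.get("disorder")
        if not spec:
            logger.warning("disorder stage skipped: no tracks configured")
            return
        tracks = core_io.load_disorder_tracks(spec["tracks"])
        scores = pd.DataFrame([mean_disorder(t).__dict__ for t in tracks.values()])
        write_table(scores, out / "disorder_scores.tsv", analysis, header)
        if "assignments" in spec and len(conditions) >= 2:
            assignments = pd.read_csv(spec["assignments"], sep="\t", comment="#")
            res = unique_condition_proteins(
                assignments, conditions[0], conditions[1], tracks
            )
            rows = [
                {"test": name, "statistic": s, "p_value": p}
                for name, (s, p) in _disorder_tests(res).items()
            ]
            write_table(
                pd.DataFrame(rows), out / "disorder_tests.tsv", analysis, header
            )

    stage("disorder")(_disorder)

    manifest["stage_counts"] = counts
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


def _disorder_tests(res: dict) -> dict:
    out = {}
    a, b = res.get("scores_a"), res.get("scores_b")
    if a is not None and b is not None and len(a) >= 2 and len(b) >= 2:
        out["welch_t"] = welch_t(a, b)
        out["mann_whitney_u"] = mann_whitney_u(a, b)
    return out


def _input_paths(config: dict) -> list[str]:
    paths = []
    if "peptides" in config:
        paths.append(config["peptides"]["path"])
    if "fasta" in config.get("substrate", {}):
        paths.append(config["substrate"]["fasta"])
    for key in ("tracks", "assignments"):
        if key in config.get("disorder", {}) or {}:
            paths.append(config["disorder"][key])
    return paths


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError(f"{path} does not hold a mapping")
    return config
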