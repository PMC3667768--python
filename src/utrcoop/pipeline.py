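"""End-to-end orchestration of the analysis stages.

Stage order follows the scientific narrative: conservation-gated motif
selection, positional localization, RBP-miRNA co-localization calling,
decay/conservation group comparisons, secondary-structure rescue, and
seed-motif hybridization scoring.  Every constant of the procedure (the
+/-10 nt conservation window, 50 nt proximity, 10,000 permutations,
FDR 0.05, 5 nt pair-window flanks, 1 nt mask flank, -1 kcal/mol open rule,
top-25% expression cut, the 0.6-precision/10-hit gate, the 200/10/3 shuffle
counts, and the 2/0/-1 alignment scoring) surfaces as a named, defaulted
configuration parameter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import colocalization as coloc
from . import conservation as cons
from . import decay as dec
from . import hybridize as hyb
from . import localization as loc
from . import structure as struct
from .core import MotifConsensus, SiteCall, scan_motif_sites
from .io import Dataset, load_dataset, write_bed_sites
from .simulate import SimConfig, generate_dataset, write_dataset

log = logging.getLogger(__name__)

STAGES = ("gate", "localize", "colocalize", "decay", "rescue", "hybridize")


@dataclass
class AnalysisConfig:
    """Analysis-stage parameters (defaults are the published procedure)."""

    seed: int = 0
    conservation_window: int = 10
    proximal_nt: int = 50
    n_permutations: int = 10000
    fdr: float = 0.05
    expression_quantile: float = 0.25
    gate_precision: float = 0.6
    gate_min_hits: int = 10
    n_shuffles_raw: int = 200
    similarity_cut: float = 0.10
    hit_tolerance: float = 0.20
    max_controls: int = 10
    min_controls: int = 3
    pvalue_mode: str = "raw"
    engine: str = "auto"
    pair_flank: int = 5
    mask_flank: int = 1
    open_energy: float = -1.0
    background_randomizations: int = 10
    max_rescue_pairs: int = 300  # per group; larger sets are subsampled


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    dataset_dir: Optional[str] = None  # None: simulate into out_dir/dataset
    skip: Tuple[str, ...] = ()
    simulate: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def load_config(path: str) -> PipelineConfig:
    """Parse a YAML config, failing fast on unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"{path}: unknown config keys {sorted(bad)}")
    for section, cls in (("simulate", SimConfig), ("analysis", AnalysisConfig)):
        sub = raw.get(section, {}) or {}
        sub_known = {f.name for f in fields(cls)}
        sub_bad = set(sub) - sub_known
        if sub_bad:
            raise ValueError(f"{path}: unknown {section} keys {sorted(sub_bad)}")
        raw[section] = cls(**sub)
    if "skip" in raw:
        bad_stages = set(raw["skip"]) - set(STAGES)
        if bad_stages:
            raise ValueError(f"{path}: unknown stages in skip: {sorted(bad_stages)}")
        raw["skip"] = tuple(raw["skip"])
    cfg = PipelineConfig(**raw)
    cfg.simulate.seed = cfg.simulate.seed or cfg.seed
    cfg.analysis.seed = cfg.analysis.seed or cfg.seed
    return cfg


@dataclass
class RunManifest:
    """What a run did: config snapshot, inputs, timings, outputs, seeds."""

    config: dict
    input_checksums: Dict[str, str] = field(default_factory=dict)
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    seeds: Dict[str, int] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)


def _checksums(directory: str) -> Dict[str, str]:
    out = {}
    for name in sorted(os.listdir(directory)):
        p = os.path.join(directory, name)
        if os.path.isfile(p):
            with open(p, "rb") as fh:
                out[name] = hashlib.sha256(fh.read()).hexdigest()[:16]
    return out


# ---------------------------------------------------------------------------
# stage implementations (each returns report paths and updates shared state)


def stage_gate(ds: Dataset, acfg: AnalysisConfig, out: str, state: dict) -> List[str]:
    """Conservation gating: BLS site tables, precision curves, pass/fail."""
    rows, outputs = [], []
    state["gate"] = {}
    for motif in ds.motifs:
        res = cons.evaluate_motif_conservation(
            motif,
            ds.utrs,
            ds.tree,
            seed=acfg.seed,
            window=acfg.conservation_window,
            n_raw=acfg.n_shuffles_raw,
            similarity_cut=acfg.similarity_cut,
            hit_tolerance=acfg.hit_tolerance,
            max_keep=acfg.max_controls,
            min_keep=acfg.min_controls,
        )
        res.passed = res.passed and cons.gate_rbp_motif(
            res.curve, acfg.gate_precision, acfg.gate_min_hits
        ) if res.curve is not None else False
        state["gate"][motif.name] = res
        bed = os.path.join(out, f"sites_{motif.name}.bed")
        write_bed_sites(res.sites, bed)
        outputs.append(bed)
        if res.curve is not None:
            curve_path = os.path.join(out, f"precision_{motif.name}.tsv")
            res.curve.to_frame().to_csv(curve_path, sep="\t", index=False)
            outputs.append(curve_path)
        rows.append(
            {
                "motif": motif.name,
                "pattern": motif.pattern,
                "eligible": res.controls.eligible,
                "n_controls": len(res.controls.motifs),
                "canonical_hits": len(res.sites),
                "passed": res.passed,
            }
        )
    summary = os.path.join(out, "gate_summary.tsv")
    pd.DataFrame(rows).to_csv(summary, sep="\t", index=False)
    outputs.append(summary)
    return outputs


def _gated_motifs(ds: Dataset, state: dict) -> List[MotifConsensus]:
    if "gate" not in state:  # gate stage skipped: use all motifs, plain scan
        state["gate"] = {}
        for motif in ds.motifs:
            sites = [
                s for u in ds.utrs for s in scan_motif_sites(u.ref_seq, motif, u.transcript_id)
            ]
            controls = cons.generate_control_motifs(motif, ds.utrs, seed=0)
            state["gate"][motif.name] = cons.MotifGateResult(
                motif, controls, None, True, sites
            )
    return [state["gate"][m.name].motif for m in ds.motifs if state["gate"][m.name].passed]


def stage_localize(ds: Dataset, acfg: AnalysisConfig, out: str, state: dict) -> List[str]:
    """Decile and end-window positional profiles with binomial enrichment."""
    outputs = []
    lengths = {u.transcript_id: u.ref_length for u in ds.utrs}
    prof_rows, test_rows = [], []
    for motif in _gated_motifs(ds, state):
        res = state["gate"][motif.name]
        for klass in loc.LENGTH_CLASSES:
            try:
                prof = loc.decile_site_fractions(res.sites, lengths, klass)
            except ValueError:
                continue
            prof_rows.append(prof.to_frame().assign(motif=motif.name))
            ctrl_profiles = []
            for ctrl in res.controls.motifs:
                csites = [
                    s
                    for u in ds.utrs
                    for s in scan_motif_sites(u.ref_seq, ctrl, u.transcript_id)
                ]
                try:
                    ctrl_profiles.append(loc.decile_site_fractions(csites, lengths, klass))
                except ValueError:
                    pass
            if ctrl_profiles:
                pvals = loc.positional_enrichment_test(prof, ctrl_profiles)
                for b, p in enumerate(pvals):
                    test_rows.append(
                        {"motif": motif.name, "length_class": klass, "bin": b, "p_bonferroni": p}
                    )
        try:
            p5, p3 = loc.end_window_fractions(res.sites, lengths)
            prof_rows.append(p5.to_frame().assign(motif=motif.name))
            prof_rows.append(p3.to_frame().assign(motif=motif.name))
        except ValueError:
            pass
    if prof_rows:
        path = os.path.join(out, "localization_profiles.tsv")
        pd.concat(prof_rows, ignore_index=True).to_csv(path, sep="\t", index=False)
        outputs.append(path)
    if test_rows:
        path = os.path.join(out, "localization_enrichment.tsv")
        pd.DataFrame(test_rows).to_csv(path, sep="\t", index=False)
        outputs.append(path)
    au_path = os.path.join(out, "au_decile_profile.tsv")
    loc.au_decile_profile(ds.utrs).to_csv(au_path, sep="\t", index=False)
    outputs.append(au_path)
    return outputs


def _scan_family_sites(ds: Dataset) -> Dict[str, Dict[str, List[SiteCall]]]:
    """{seed_type: {family_id: sites}} over all reference UTRs."""
    out: Dict[str, Dict[str, List[SiteCall]]] = {"m8": {}, "1a": {}}
    for fam in ds.families:
        for seed_type, motif in (("m8", fam.m8_site), ("1a", fam.a1_site)):
            sites: List[SiteCall] = []
            for u in ds.utrs:
                sites.extend(scan_motif_sites(u.ref_seq, motif, u.transcript_id))
            out[seed_type][fam.family_id] = sites
    return out


def stage_colocalize(ds: Dataset, acfg: AnalysisConfig, out: str, state: dict) -> List[str]:
    """Interaction tables, interacting-miRNA calls, window enrichment."""
    outputs = []
    lengths = {u.transcript_id: u.ref_length for u in ds.utrs}
    state.setdefault("family_sites", _scan_family_sites(ds))
    state["interacting"] = {}
    state["interaction_tables"] = {}
    for motif in _gated_motifs(ds, state):
        rbp_sites = state["gate"][motif.name].sites
        table = coloc.build_interaction_table(
            motif.name,
            rbp_sites,
            state["family_sites"],
            ds.families,
            lengths,
            n_perm=acfg.n_permutations,
            seed=acfg.seed,
            pvalue_mode=acfg.pvalue_mode,
        )
        called = coloc.call_interacting_mirnas(table, fdr=acfg.fdr)
        state["interacting"][motif.name] = called
        state["interaction_tables"][motif.name] = table
        tpath = os.path.join(out, f"interaction_{motif.name}.tsv")
        table.to_csv(tpath, sep="\t", index=False)
        outputs.append(tpath)
        mat = coloc.window_enrichment_matrix(table, n_perm=acfg.n_permutations)
        mpath = os.path.join(out, f"window_enrichment_{motif.name}.tsv")
        mat.to_csv(mpath, sep="\t")
        outputs.append(mpath)
    calls = pd.DataFrame(
        [
            {"rbp": rbp, "family": fam}
            for rbp, fams in state["interacting"].items()
            for fam in sorted(fams)
        ],
        columns=["rbp", "family"],
    )
    cpath = os.path.join(out, "interacting_mirnas.tsv")
    calls.to_csv(cpath, sep="\t", index=False)
    outputs.append(cpath)
    return outputs


def _pooled_family_sites(state: dict) -> Dict[str, List[SiteCall]]:
    pooled: Dict[str, List[SiteCall]] = {}
    for by_family in state["family_sites"].values():
        for fam, sites in by_family.items():
            pooled.setdefault(fam, []).extend(sites)
    return pooled


def stage_decay(ds: Dataset, acfg: AnalysisConfig, out: str, state: dict) -> List[str]:
    """Four-group half-life and site-conservation comparisons."""
    if ds.halflife is None:
        log.warning("no half-life table; decay stage skipped")
        return []
    outputs = []
    state.setdefault("family_sites", _scan_family_sites(ds))
    expressed = dec.filter_expressed_mirnas(ds.expression, acfg.expression_quantile)
    pooled = _pooled_family_sites(state)
    rows, prows = [], []
    state["decay_assignments"] = {}
    for motif in _gated_motifs(ds, state):
        rbp_sites = state["gate"][motif.name].sites
        interacting = state.get("interacting", {}).get(motif.name, set())
        assignments = dec.classify_transcripts_by_pairing(
            rbp_sites, pooled, interacting, expressed
        )
        state["decay_assignments"][motif.name] = assignments
        values = dec.group_values(assignments, ds.halflife.values)
        comp = dec.compare_group_values(values, direction=ds.halflife.kind)
        rows.append(comp.summary.assign(rbp=motif.name, measure=ds.halflife.kind))
        for (a, b), p in comp.pvalues.items():
            prows.append(
                {"rbp": motif.name, "measure": ds.halflife.kind, "group_a": a, "group_b": b, "p": p}
            )
        bls_groups = dec.site_conservation_by_group(
            rbp_sites, pooled, interacting, expressed
        )
        comp_bls = dec.compare_group_values(bls_groups, direction="bls")
        rows.append(comp_bls.summary.assign(rbp=motif.name, measure="bls"))
        for (a, b), p in comp_bls.pvalues.items():
            prows.append(
                {"rbp": motif.name, "measure": "bls", "group_a": a, "group_b": b, "p": p}
            )
        apath = os.path.join(out, f"decay_groups_{motif.name}.tsv")
        pd.DataFrame(
            {"transcript_id": list(assignments), "group": list(assignments.values())}
        ).to_csv(apath, sep="\t", index=False)
        outputs.append(apath)
    spath = os.path.join(out, "decay_summary.tsv")
    pd.concat(rows, ignore_index=True).to_csv(spath, sep="\t", index=False)
    ppath = os.path.join(out, "decay_pvalues.tsv")
    pd.DataFrame(prows).to_csv(ppath, sep="\t", index=False)
    outputs.extend([spath, ppath])
    return outputs


def _collect_pairs(
    rbp_sites: Sequence[SiteCall],
    fam_sites: Dict[str, List[SiteCall]],
    fam_subset: Set[str],
    utr_seq: Dict[str, str],
    acfg: AnalysisConfig,
) -> List[struct.PairWindow]:
    by_tid: Dict[str, List[SiteCall]] = {}
    for r in rbp_sites:
        by_tid.setdefault(r.transcript_id, []).append(r)
    windows = []
    for fam in sorted(fam_subset):
        for m in fam_sites.get(fam, ()):
            for r in by_tid.get(m.transcript_id, ()):
                gap, _ = coloc.pair_gap_and_window(r, m)
                if gap <= acfg.proximal_nt:
                    try:
                        w, riv, miv = struct.extract_pair_window(
                            utr_seq[m.transcript_id], r, m, acfg.pair_flank
                        )
                        # reject pairs whose mask would cover the seed site
                        a = max(0, riv[0] - acfg.mask_flank)
                        b = min(len(w), riv[1] + acfg.mask_flank)
                        if a < miv[1] and miv[0] < b:
                            continue
                        windows.append((w, riv, miv))
                    except ValueError:
                        continue
    return windows


def stage_rescue(ds: Dataset, acfg: AnalysisConfig, out: str, state: dict) -> List[str]:
    """Rescue-count histograms for interacting vs non-interacting pairs."""
    outputs = []
    state.setdefault("family_sites", _scan_family_sites(ds))
    pooled = _pooled_family_sites(state)
    utr_seq = {u.transcript_id: u.ref_seq for u in ds.utrs}
    rng = np.random.default_rng(acfg.seed)
    state["rescue"] = {}
    for motif in _gated_motifs(ds, state):
        rbp_sites = state["gate"][motif.name].sites
        interacting = state.get("interacting", {}).get(motif.name, set())
        non_interacting = set(pooled) - interacting
        groups = {}
        for label, fams in (("interacting", interacting), ("non_interacting", non_interacting)):
            pairs = _collect_pairs(rbp_sites, pooled, fams, utr_seq, acfg)
            if len(pairs) > acfg.max_rescue_pairs:
                idx = rng.choice(len(pairs), acfg.max_rescue_pairs, replace=False)
                pairs = [pairs[i] for i in sorted(idx)]
            groups[label] = pairs
        counts = {
            label: struct.rescue_counts_for_pairs(pairs, acfg.engine)
            for label, pairs in groups.items()
        }
        result: Dict[str, object] = {"counts": counts}
        if counts["interacting"] and counts["non_interacting"]:
            result["p_int_vs_nonint"] = struct.compare_rescue_distributions(
                counts["interacting"], counts["non_interacting"]
            )
        if groups["interacting"]:
            bg = struct.rescue_background(
                groups["interacting"],
                n=acfg.background_randomizations,
                engine=acfg.engine,
                seed=acfg.seed,
            )
            result["background"] = bg
            bpath = os.path.join(out, f"rescue_background_{motif.name}.tsv")
            bg.to_csv(bpath, sep="\t", index=False)
            outputs.append(bpath)
        state["rescue"][motif.name] = result
        # pair windows as FASTA with a companion site-interval TSV, plus the
        # folded dot-bracket structures (interacting group)
        if groups["interacting"]:
            seqs, iv_rows, db_lines = {}, [], []
            for i, (w, riv, miv) in enumerate(groups["interacting"]):
                name = f"{motif.name}_pair{i:04d}"
                seqs[name] = w
                iv_rows.append(
                    {"window": name, "rbp_start": riv[0], "rbp_end": riv[1],
                     "mirna_start": miv[0], "mirna_end": miv[1]}
                )
                fr = struct.fold(w, acfg.engine, acfg.open_energy)
                db_lines.append(f">{name}\n{w}\n{fr.structure} ({fr.energy:.2f})\n")
            from .io import write_fasta

            fpath = os.path.join(out, f"pair_windows_{motif.name}.fa")
            write_fasta(seqs, fpath)
            ipath = os.path.join(out, f"pair_intervals_{motif.name}.tsv")
            pd.DataFrame(iv_rows).to_csv(ipath, sep="\t", index=False)
            dpath = os.path.join(out, f"pair_structures_{motif.name}.txt")
            with open(dpath, "w") as fh:
                fh.writelines(db_lines)
            outputs.extend([fpath, ipath, dpath])
        hist_rows = []
        for label, cs in counts.items():
            for c in cs:
                hist_rows.append({"rbp": motif.name, "group": label, "rescue": c})
        hpath = os.path.join(out, f"rescue_counts_{motif.name}.tsv")
        pd.DataFrame(hist_rows, columns=["rbp", "group", "rescue"]).to_csv(
            hpath, sep="\t", index=False
        )
        outputs.append(hpath)
    return outputs


def stage_hybridize(ds: Dataset, acfg: AnalysisConfig, out: str, state: dict) -> List[str]:
    """Seed vs reversed-motif hybridization scores per family."""
    outputs = []
    state["hybridization"] = {}
    for motif in _gated_motifs(ds, state):
        interacting = state.get("interacting", {}).get(motif.name, set())
        scores = hyb.score_families(ds.families, motif)
        rows = [
            {
                "family": fid,
                "rbp": motif.name,
                "score": sc.score,
                "interacting": fid in interacting,
                "alignment_seed": sc.alignment[0],
                "alignment_motif": sc.alignment[1],
            }
            for fid, sc in scores.items()
        ]
        path = os.path.join(out, f"hybridization_{motif.name}.tsv")
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        outputs.append(path)
        result: Dict[str, object] = {"scores": scores}
        if interacting and (set(scores) - interacting):
            controls = state["gate"][motif.name].controls.motifs
            result.update(
                hyb.score_groups(ds.families, motif, interacting, controls)
            )
        state["hybridization"][motif.name] = result
    return outputs


_STAGE_FUNCS = {
    "gate": stage_gate,
    "localize": stage_localize,
    "colocalize": stage_colocalize,
    "decay": stage_decay,
    "rescue": stage_rescue,
    "hybridize": stage_hybridize,
}


def run_pipeline(
    config: PipelineConfig, dataset: Optional[Dataset] = None
) -> Tuple[RunManifest, dict]:
    """Run all (non-skipped) stages; returns the manifest and shared state."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    if dataset is None:
        if config.dataset_dir and os.path.exists(
            os.path.join(config.dataset_dir, "tree.nwk")
        ):
            dataset = load_dataset(config.dataset_dir)
            manifest.input_checksums = _checksums(config.dataset_dir)
        else:
            ds_dir = config.dataset_dir or os.path.join(config.out_dir, "dataset")
            dataset, truth = generate_dataset(config.simulate)
            write_dataset(dataset, ds_dir, truth)
            manifest.input_checksums = _checksums(ds_dir)
            manifest.seeds["simulate"] = config.simulate.seed
    manifest.seeds["analysis"] = config.analysis.seed
    state: dict = {}
    for stage in STAGES:
        if stage in config.skip:
            log.info("skipping stage %s", stage)
            continue
        t0 = time.time()
        outputs = _STAGE_FUNCS[stage](dataset, config.analysis, config.out_dir, state)
        manifest.stage_seconds[stage] = round(time.time() - t0, 3)
        manifest.outputs.extend(outputs)
        log.info("stage %s done in %.1fs", stage, manifest.stage_seconds[stage])
    missing = [p for p in manifest.outputs if not os.path.exists(p)]
    if missing:
        raise RuntimeError(f"stage outputs missing: {missing}")
    manifest.write(os.path.join(config.out_dir, "manifest.json"))
    return manifest, state
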