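"""End-to-end orchestration: stats -> structure -> repeats -> repeat tree ->
distances -> markers -> indels -> inversions, with TSV/JSON outputs and a run
manifest.

The pipeline consumes either a simulated bundle (config key ``simulate``) or
annotated GenBank records plus a pre-computed whole-genome alignment.  Every
stage writes one table and one machine-readable JSON; any stage failure
raises :class:`StageError` naming the stage, keeping earlier outputs on disk.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import divergence, genome, indels, parsimony, repeats
from .simulate import (
    BAMBOO_GROUPS,
    BAMBOO_TREE,
    bamboo_like_config,
    plant_markers,
    simulate as _simulate,
)
from .quadripartite import detect_quadripartite, junction_report

DEFAULTS = {
    "min_ir": 10_000,
    "bootstrap_reps": 200,
    "min_region_len": 350,
    "subfamily_min_len": 200,
    "window": 100,
    "step": 25,
    "min_dispersed": 30,
    "min_tandem": 15,
    "min_palindromic": 20,
    "max_gap": 3000,
    "identity": 0.90,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonify(x) for x in obj]
    return obj


def _write_json(path, obj):
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def load_inputs(config: dict):
    """Returns (records dict, alignment or None, reference tree or None, extras)."""
    if "simulate" in config:
        s = dict(config["simulate"])
        scale = s.get("scale", 1.0)
        cfg = bamboo_like_config(
            scale=scale,
            tree=s.get("tree", BAMBOO_TREE),
            with_plants=s.get("with_plants", True),
        )
        if s.get("hot_regions"):
            cfg = plant_markers(cfg, s["hot_regions"], s.get("fold", 5.0))
        res = _simulate(cfg, seed=int(s.get("seed", config.get("seed", 0))))
        return res.records, res.alignment, res.tree, {"simulation": res}
    records = {}
    for p in config.get("genbank", []):
        rec = genome.read_genbank(p)
        records[rec.id] = rec
    aln = None
    if config.get("alignment"):
        aln = divergence.AlignedSet.from_fasta(config["alignment"])
    tree = None
    if config.get("tree"):
        tree = parsimony.read_newick(config["tree"])
    return records, aln, tree, {}


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULTS, **config.get("params", {})}
    unknown = set(config) - {
        "simulate", "genbank", "alignment", "tree", "groups", "reference",
        "outgroup", "seed", "params",
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(_jsonify(config), sort_keys=True).encode()
        ).hexdigest(),
        "params": params,
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"].append(name)
            except Exception as exc:  # noqa: BLE001
                _write_json(outdir / "manifest.json", manifest)
                raise StageError(name, exc) from exc
        return deco

    records, aln, tree, extras = load_inputs(config)
    if "simulation" in extras and "min_ir" not in config.get("params", {}):
        # scaled-down simulated genomes have proportionally shorter IR arms
        arch = extras["simulation"].config.architecture
        params["min_ir"] = max(200, arch.ir_len // 2)
    taxa = list(records)
    reference = config.get("reference", taxa[0])
    outgroup = config.get("outgroup", taxa[0])
    groups = config.get("groups")
    if groups is None and set(taxa) <= set(BAMBOO_GROUPS):
        groups = {t: BAMBOO_GROUPS[t] for t in taxa}

    quads = {}
    state: dict = {}

    @stage("stats")
    def _stats():
        rows = [
            {"genome": t, **genome.genome_stats(records[t])} for t in taxa
        ]
        pd.DataFrame(rows).to_csv(outdir / "stats.tsv", sep="\t", index=False)
        _write_json(outdir / "stats.json", rows)

    @stage("structure")
    def _structure():
        rows = []
        for t in taxa:
            q = detect_quadripartite(records[t].seq, min_ir=params["min_ir"])
            assert q.tiles_genome()
            quads[t] = q
            jr = junction_report(q, records[t])
            row = {
                "genome": t,
                "lsc_len": q.lsc_length,
                "ssc_len": q.ssc_length,
                "ir_len": q.ir_length,
            }
            for e in jr.entries:
                key = e.junction.replace("/", "_")
                row[f"{key}_gene"] = e.gene
                row[f"{key}_extension"] = e.extension_into_ir
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "structure.tsv", sep="\t", index=False)
        _write_json(outdir / "structure.json", rows)

    @stage("repeats")
    def _repeats():
        sets = []
        rows = []
        for t in taxa:
            rs = repeats.scan_genome(
                records[t],
                quads.get(t),
                min_dispersed=params["min_dispersed"],
                min_tandem=params["min_tandem"],
                min_palindromic=params["min_palindromic"],
                max_gap=params["max_gap"],
                min_identity=params["identity"],
            )
            sets.append(rs)
            for m in rs:
                rows.append(
                    {
                        "genome": t,
                        "type": m.type,
                        "unit_length": m.unit_length,
                        "identity": round(m.identity, 3),
                        "location": m.location_class,
                        "copies": ";".join(f"{s}-{e}({st:+d})" for s, e, st in m.copies),
                        "context": ";".join("|".join(c) for c in m.context),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "repeats.tsv", sep="\t", index=False)
        table = repeats.shared_repeats(sets)
        _write_json(
            outdir / "shared_repeats.json",
            {
                "shared": {"+".join(sorted(k)): v for k, v in table.shared.items()},
                "unique": table.unique,
                "total_motifs": sum(len(s) for s in sets),
            },
        )
        M = repeats.to_binary_matrix(sets)
        parsimony.write_nexus(M, outdir / "repeat_matrix.nex")
        state["repeat_matrix"] = M
        state["repeat_sets"] = sets

    @stage("repeat-tree")
    def _repeat_tree():
        M = state["repeat_matrix"]
        if not 4 <= M.n_taxa <= parsimony.MAX_EXHAUSTIVE_TAXA:
            _write_json(outdir / "repeat_tree.json", {"skipped": "taxon count"})
            return
        opts, score = parsimony.exhaustive_search(M)
        support = parsimony.bootstrap(
            M, reps=params["bootstrap_reps"], seed=seed
        )
        best = opts[0]
        parsimony.write_newick(best, outdir / "repeat_tree.nwk")
        _write_json(
            outdir / "repeat_tree.json",
            {
                "n_optimal": len(opts),
                "steps": score.s,
                "ci": round(score.ci, 3),
                "ri": round(score.ri, 3),
                "bootstrap": {
                    "+".join(sorted(b)): round(v, 1)
                    for b, v in support.items()
                    if b in best.bipartitions()
                },
            },
        )
        state["repeat_tree"] = best

    @stage("distance")
    def _distance():
        if aln is None:
            _write_json(outdir / "distance.json", {"skipped": "no alignment"})
            return
        summ = divergence.p_distance(aln, groups=groups)
        summ.matrix.round(6).to_csv(outdir / "distance.tsv", sep="\t")
        _write_json(
            outdir / "distance.json",
            {
                "overall_mean": round(summ.overall_mean, 4),
                "within": {k: round(v, 4) for k, v in summ.within.items()},
                "between": {
                    "|".join(k): round(v, 4) for k, v in summ.between.items()
                },
            },
        )
        prof = divergence.identity_profile(
            aln, reference, window=params["window"], step=params["step"]
        )
        prof.round(2).to_csv(outdir / "identity_profile.tsv", sep="\t")
        state["distance"] = summ

    @stage("markers")
    def _markers():
        if aln is None:
            _write_json(outdir / "markers.json", {"skipped": "no alignment"})
            return
        ref_rec = records[reference]
        q = quads.get(reference)
        regions = genome.partition_regions(
            ref_rec, min_len=params["min_region_len"],
            single_copy_only=q is not None, quadripartite=q,
        )
        region_alns = divergence.extract_region_alignments(aln, reference, regions)
        stats = []
        for r in regions:
            a = region_alns.get(r.name)
            if a is None:
                continue
            stats.append(
                divergence.region_variability(a, count_indels=True, name=r.name, cls=r.cls)
            )
        noncoding = [s for s in stats if s.cls == "noncoding"]
        coding = [s for s in stats if s.cls == "coding"]
        ranked, counts = divergence.rank_markers(noncoding)
        ranked.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        fits = {}
        for nm, group in (("noncoding", noncoding), ("coding", coding)):
            xs = [100.0 * s.variable_sites / s.length for s in group]
            ys = [s.pi_pct for s in group]
            try:
                fit = divergence.fit_linear(xs, ys)
                fits[nm] = {
                    "slope": round(fit.slope, 4),
                    "r_squared": round(fit.r_squared, 4),
                    "p_value": fit.p_value,
                    "n": len(xs),
                }
            except ValueError as exc:
                fits[nm] = {"skipped": str(exc)}
        _write_json(
            outdir / "markers.json",
            {
                "top": ranked.region.head(20).tolist(),
                **counts,
                "mean_noncoding_variation": round(
                    float(np.mean([s.variation_pct for s in noncoding])), 3
                ) if noncoding else None,
                "mean_coding_variation": round(
                    float(np.mean([s.variation_pct for s in coding])), 3
                ) if coding else None,
                "regression": fits,
            },
        )
        state["marker_stats"] = stats
        state["ranked"] = ranked

    @stage("indels")
    def _indels():
        if aln is None or outgroup not in aln.taxa:
            _write_json(outdir / "indels.json", {"skipped": "no alignment/outgroup"})
            return
        ref_rec = records[reference]
        coding_regions = [
            r for r in genome.partition_regions(ref_rec, min_len=30)
            if r.cls == "coding"
        ]
        gene_alns = divergence.extract_region_alignments(aln, reference, coding_regions)
        events = indels.extract_exon_indels(gene_alns, outgroup=outgroup)
        if tree is not None:
            events = indels.classify_events(events, tree, outgroup)
        rows = [
            {
                "gene": e.gene,
                "position": e.position,
                "size": e.size,
                "polarity": e.polarity,
                "derived_taxa": ";".join(e.derived_taxa),
                "classification": e.classification,
                "origins": e.origins,
            }
            for e in events
        ]
        pd.DataFrame(rows).to_csv(outdir / "indels.tsv", sep="\t", index=False)
        n_syn = sum(1 for e in events if e.classification == "synapomorphic")
        n_hom = sum(1 for e in events if e.classification == "homoplasious")
        _write_json(
            outdir / "indels.json",
            {
                "n_events": len(events),
                "n_genes": len({e.gene for e in events}),
                "n_synapomorphic": n_syn,
                "n_homoplasious": n_hom,
            },
        )
        state["indel_events"] = events

    @stage("inversions")
    def _inversions():
        if aln is None:
            _write_json(outdir / "inversions.json", {"skipped": "no alignment"})
            return
        events = indels.detect_small_inversions(aln, reference=reference)
        rows = [
            {
                "location": e.location,
                "segment": f"{e.segment[0]}-{e.segment[1]}",
                "arm_len": e.arms[0][1] - e.arms[0][0] + 1,
                "taxa": ";".join(e.taxa),
                "inverted_identity": round(e.inverted_identity, 3),
                "direct_identity": round(e.direct_identity, 3),
            }
            for e in events
        ]
        pd.DataFrame(rows).to_csv(outdir / "inversions.tsv", sep="\t", index=False)
        _write_json(outdir / "inversions.json", {"n_inversions": len(rows)})
        state["inversion_events"] = events

    _write_json(outdir / "manifest.json", manifest)
    state["manifest"] = manifest
    state["records"] = records
    state["alignment"] = aln
    state["quadripartite"] = quads
    state.update(extras)
    return state
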