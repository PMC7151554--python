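"""End-to-end orchestration: simulate -> search -> cluster -> merge ->
estimate -> annotate -> report.

A single :class:`PipelineConfig` carries every threshold of the protocol
(E-value 1e-10; global identity 25%/40%; reciprocal-best-cluster
correspondence 0.5 at local identity 30%; annotation coverage 80%; prokaryote
family size >= 5; eukaryote species span >= 2; replicate count and bacterial
sample size), all defaulting to the published survey values.  The
:class:`RunManifest` records per-stage accounting counters and enforces the
bookkeeping identities

``n_epc = n_bacterial_only + n_archaeal_only + n_dual`` and
``n_final = n_bacterial_only + n_archaeal_only - n_recheck_excluded``

(the desk-scale mirror of the survey's 2,587 = 1,853 + 515 + 219 and
2,368 - 266 = 2,102 ledger), plus sequence mass conservation across the
clustering stages.  Reruns with the same config and seed reproduce identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import align
from .align import DEFAULT_GLOBAL, DEFAULT_SCORING, GlobalScoring, ScoringScheme
from .ancestry import (
    AncestryEstimate,
    DownsampleScheme,
    estimate_proportions,
    group_summary,
    size_correlation,
)
from .annotate import (
    AnnotationReference,
    annotate_epcs,
    category_origin_summary,
    presence_absence_matrix,
)
from .epc import EPC, classify_epc, link_clusters, recheck_exclusive
from .mcl import ProteinFamily, filter_families, mcl_cluster
from .rbh import rbh_graph_for_domain
from .simulate import (
    GenomeRecord,
    SimulationConfig,
    TruthTable,
    make_annotation_reference,
    simulate_dataset,
)

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    evalue_cutoff: float = 1e-10
    min_global_identity_prok: float = 25.0
    min_global_identity_euk: float = 40.0
    min_correspondence: float = 0.5
    min_local_identity: float = 30.0
    min_annotation_coverage: float = 80.0
    min_prok_family_size: int = 5
    min_euk_species: int = 2
    mcl_inflation: float = 2.0
    mcl_prune_threshold: float = 1e-5
    n_replicates: int = 1000
    sample_size: Optional[int] = None  # default: number of archaea
    recheck: bool = True
    correspondence_denominator: str = "hit_bearing"
    annotation_reference_identity: float = 60.0
    run_annotation: bool = True
    run_presence_matrix: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["simulation"]["presence_prob"] = dict(self.simulation.presence_prob)
        data["simulation"]["genus_sizes"] = list(self.simulation.genus_sizes)
        data["simulation"]["parasite_ids"] = list(self.simulation.parasite_ids)
        data["simulation"]["seq_length_range"] = list(self.simulation.seq_length_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("simulation", {})
        if "seq_length_range" in sim:
            sim["seq_length_range"] = tuple(sim["seq_length_range"])
        return cls(simulation=SimulationConfig(**sim), **data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    n_sequences: Dict[str, int] = field(default_factory=dict)
    n_families: Dict[str, int] = field(default_factory=dict)
    n_dropped_clusters: Dict[str, int] = field(default_factory=dict)
    n_dropped_sequences: Dict[str, int] = field(default_factory=dict)
    n_euk_specific: int = 0
    n_epc: int = 0
    n_bacterial_only: int = 0
    n_archaeal_only: int = 0
    n_dual: int = 0
    n_ambiguous: int = 0
    n_recheck_excluded: int = 0
    n_final: int = 0
    n_in_families: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_epc != self.n_bacterial_only + self.n_archaeal_only + self.n_dual:
            raise AssertionError(
                "accounting identity violated: n_epc != bacterial + archaeal + dual"
            )
        expected_final = self.n_bacterial_only + self.n_archaeal_only - self.n_recheck_excluded
        if self.n_final != expected_final:
            raise AssertionError(
                "accounting identity violated: n_final != exclusive - recheck_excluded"
            )
        for domain, total in self.n_sequences.items():
            in_families = self.n_in_families.get(domain, 0)
            dropped = self.n_dropped_sequences.get(domain, 0)
            if in_families + dropped != total:
                raise AssertionError(f"sequence mass not conserved for {domain}")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: List[GenomeRecord]
    truth: Optional[TruthTable]
    families: Dict[str, List[ProteinFamily]]
    epcs: List[EPC]  # all classified EPCs incl. dual/ambiguous/excluded
    estimates: List[AncestryEstimate]
    naive_estimates: List[AncestryEstimate]
    group_table: pd.DataFrame
    category_table: pd.DataFrame
    presence_matrix: pd.DataFrame
    manifest: RunManifest
    dropped_clusters: Dict[str, List[Set[str]]] = field(default_factory=dict)

    @property
    def scored_epcs(self) -> List[EPC]:
        return [e for e in self.epcs if e.origin in ("bacterial", "archaeal")]

    def mean_p_bacterial(self, naive: bool = False) -> float:
        ests = self.naive_estimates if naive else self.estimates
        vals = [e.p_bacterial for e in ests if e.p_bacterial is not None]
        if not vals:
            raise ValueError("no genome with defined proportions")
        return float(np.mean(vals))


def _best_hits_per_domain(
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    scores: np.ndarray,
    pass_a: np.ndarray,
    domains_b: Sequence[str],
) -> Dict[str, Dict[str, int]]:
    """For each query (rows), best passing subject column per subject domain."""
    out: Dict[str, Dict[str, int]] = {}
    domains_b = np.asarray(domains_b)
    for dom in sorted(set(domains_b.tolist())):
        cols = np.nonzero(domains_b == dom)[0]
        if len(cols) == 0:
            continue
        sub = np.where(pass_a[:, cols], scores[:, cols], -1)
        best = np.argmax(sub, axis=1)
        for i, qid in enumerate(ids_a):
            if sub[i, best[i]] >= 0:
                out.setdefault(qid, {})[dom] = int(cols[best[i]])
    return out


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> PipelineResult:
    """Execute every stage on a simulated dataset and return all artifacts."""
    scoring = ScoringScheme(evalue_cutoff=config.evalue_cutoff)
    gscoring = DEFAULT_GLOBAL

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    genomes, truth = simulate_dataset(sim)
    seq_lookup: Dict[str, str] = {}
    genome_of: Dict[str, str] = {}
    domain_of_genome = {g.genome_id: g.domain for g in genomes}
    for g in genomes:
        for sid, seq in g.proteins.items():
            seq_lookup[sid] = seq
            genome_of[sid] = g.genome_id

    # ---- within-domain clustering ------------------------------------------
    families: Dict[str, List[ProteinFamily]] = {}
    dropped_log: Dict[str, List[Set[str]]] = {}
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    for domain in ("bacteria", "archaea", "eukaryote"):
        ids = sorted(s for s, g in genome_of.items() if domain_of_genome[g] == domain)
        manifest.n_sequences[domain] = len(ids)
        if not ids:
            families[domain] = []
            dropped_log[domain] = []
            continue
        seqs = {i: seq_lookup[i] for i in ids}
        scores = align.all_vs_all_scores([seqs[i] for i in ids], scoring=scoring)
        cutoff = (
            config.min_global_identity_euk
            if domain == "eukaryote"
            else config.min_global_identity_prok
        )
        graph = rbh_graph_for_domain(
            seqs,
            {i: genome_of[i] for i in ids},
            cutoff,
            scoring=scoring,
            scores=scores,
            ids=ids,
        )
        partition = mcl_cluster(
            graph,
            inflation=config.mcl_inflation,
            prune_threshold=config.mcl_prune_threshold,
        )
        kept, dropped = filter_families(
            partition,
            domain,
            genome_of,
            min_prok_family_size=config.min_prok_family_size,
            min_euk_species=config.min_euk_species,
        )
        families[domain] = kept
        dropped_log[domain] = dropped
        manifest.n_families[domain] = len(kept)
        manifest.n_dropped_clusters[domain] = len(dropped)
        manifest.n_in_families[domain] = sum(f.size for f in kept)
        manifest.n_dropped_sequences[domain] = sum(len(c) for c in dropped)

    # ---- interdomain best hits ---------------------------------------------
    euk_fams = families["eukaryote"]
    prok_fams = families["bacteria"] + families["archaea"]
    euk_ids = sorted(m for f in euk_fams for m in f.members)
    prok_ids = sorted(m for f in prok_fams for m in f.members)
    prok_dom = [domain_of_genome[genome_of[i]] for i in prok_ids]

    best_hits: Dict[str, Dict[str, Tuple[str, float, float]]] = {}
    inter_scores = np.zeros((len(euk_ids), len(prok_ids)), dtype=np.int32)
    if euk_ids and prok_ids:
        inter_scores = align.all_vs_all_scores(
            [seq_lookup[i] for i in euk_ids],
            [seq_lookup[i] for i in prok_ids],
            scoring,
        )
        euk_lens = np.array([len(seq_lookup[i]) for i in euk_ids])
        prok_lens = np.array([len(seq_lookup[i]) for i in prok_ids])
        prok_db = int(prok_lens.sum())
        euk_db = int(euk_lens.sum())
        pass_euk = inter_scores >= np.array(
            [align.min_score_for_evalue(L, prok_db, scoring) for L in euk_lens]
        )[:, None]
        pass_prok = inter_scores.T >= np.array(
            [align.min_score_for_evalue(L, euk_db, scoring) for L in prok_lens]
        )[:, None]

        fwd = _best_hits_per_domain(euk_ids, prok_ids, inter_scores, pass_euk, prok_dom)
        rev = _best_hits_per_domain(
            prok_ids,
            euk_ids,
            inter_scores.T,
            pass_prok,
            ["eukaryote"] * len(euk_ids),
        )
        euk_index = {s: i for i, s in enumerate(euk_ids)}
        prok_index = {s: i for i, s in enumerate(prok_ids)}
        for qid, per_dom in fwd.items():
            qi = euk_index[qid]
            entry = {}
            for dom, col in per_dom.items():
                sid = prok_ids[col]
                raw = int(inter_scores[qi, col])
                ev = align.e_value(raw, euk_lens[qi], prok_db, scoring)
                _, ident, _ = align.local_hit_details(seq_lookup[qid], seq_lookup[sid], scoring)
                entry[dom] = (sid, float(ev), ident)
            best_hits[qid] = entry
        for qid, per_dom in rev.items():
            qi = prok_index[qid]
            col = per_dom["eukaryote"]
            sid = euk_ids[col]
            raw = int(inter_scores[euk_index[sid], qi])
            ev = align.e_value(raw, prok_lens[qi], euk_db, scoring)
            _, ident, _ = align.local_hit_details(seq_lookup[qid], seq_lookup[sid], scoring)
            best_hits[qid] = {"eukaryote": (sid, float(ev), ident)}

    # ---- link, classify, recheck -------------------------------------------
    links = link_clusters(
        euk_fams,
        prok_fams,
        best_hits,
        min_correspondence=config.min_correspondence,
        min_local_identity=config.min_local_identity,
        evalue_cutoff=config.evalue_cutoff,
        denominator=config.correspondence_denominator,
    )
    links_by_fam: Dict[str, List] = {}
    for l in links:
        links_by_fam.setdefault(l.euk_family_id, []).append(l)
    prok_by_id = {f.family_id: f for f in prok_fams}
    fam_members = {f.family_id: f.members for f in prok_fams}

    def prok_homologous(fid_a: str, fid_b: str) -> bool:
        """Two prokaryote families are homologous iff some cross pair passes
        E <= cutoff and global identity >= the prokaryote cutoff."""
        mem_a, mem_b = fam_members[fid_a], fam_members[fid_b]
        sc = align.all_vs_all_scores(
            [seq_lookup[m] for m in mem_a], [seq_lookup[m] for m in mem_b], scoring
        )
        db = sum(len(seq_lookup[m]) for m in mem_b)
        for i, ma in enumerate(mem_a):
            thr = align.min_score_for_evalue(len(seq_lookup[ma]), db, scoring)
            for j, mb in enumerate(mem_b):
                if sc[i, j] >= thr:
                    gi = align.global_identity(seq_lookup[ma], seq_lookup[mb], gscoring)
                    if gi >= config.min_global_identity_prok:
                        return True
        return False

    epcs: List[EPC] = []
    n_euk_specific = 0
    eid = 0
    for ef in euk_fams:
        fam_links = links_by_fam.get(ef.family_id, [])
        if not fam_links:
            n_euk_specific += 1
            continue
        eid += 1
        epcs.append(
            classify_epc(ef, fam_links, prok_by_id, prok_homologous, f"EPC{eid:05d}")
        )

    manifest.n_euk_specific = n_euk_specific
    manifest.n_ambiguous = sum(1 for e in epcs if e.origin == "ambiguous")
    manifest.n_bacterial_only = sum(1 for e in epcs if e.origin == "bacterial")
    manifest.n_archaeal_only = sum(1 for e in epcs if e.origin == "archaeal")
    manifest.n_dual = sum(1 for e in epcs if e.origin == "dual")
    manifest.n_epc = manifest.n_bacterial_only + manifest.n_archaeal_only + manifest.n_dual

    if config.recheck:
        # hit in the other prokaryotic domain at E <= cutoff and global >= 25%
        euk_index = {s: i for i, s in enumerate(euk_ids)}
        dom_cols = {
            "bacteria": np.nonzero(np.asarray(prok_dom) == "bacteria")[0],
            "archaea": np.nonzero(np.asarray(prok_dom) == "archaea")[0],
        }
        prok_db = sum(len(seq_lookup[i]) for i in prok_ids)
        cache: Dict[Tuple[str, str], bool] = {}

        def make_checker(other_domain: str):
            cols = dom_cols[other_domain]

            def check(seq_id: str) -> bool:
                key = (seq_id, other_domain)
                if key in cache:
                    return cache[key]
                result = False
                if len(cols):
                    qi = euk_index[seq_id]
                    thr = align.min_score_for_evalue(
                        len(seq_lookup[seq_id]), prok_db, scoring
                    )
                    hits = cols[inter_scores[qi, cols] >= thr]
                    for col in hits:
                        gi = align.global_identity(
                            seq_lookup[seq_id], seq_lookup[prok_ids[col]], gscoring
                        )
                        if gi >= config.min_global_identity_prok:
                            result = True
                            break
                cache[key] = result
                return result

            return check

        checkers = {"bacterial": make_checker("archaea"), "archaeal": make_checker("bacteria")}
        epcs = [
            recheck_exclusive(e, checkers[e.origin]) if e.origin in checkers else e
            for e in epcs
        ]
    manifest.n_recheck_excluded = sum(1 for e in epcs if e.origin == "excluded_by_recheck")
    manifest.n_final = (
        manifest.n_bacterial_only + manifest.n_archaeal_only - manifest.n_recheck_excluded
    )
    manifest.validate()

    # ---- ancestry estimation -----------------------------------------------
    scored = [e for e in epcs if e.origin in ("bacterial", "archaeal")]
    bacteria = [g for g in genomes if g.domain == "bacteria"]
    archaea = {g.genome_id for g in genomes if g.domain == "archaea"}
    euk_genome_ids = sorted(
        {g for e in scored for g in e.euk_genomes}
    )
    genus_table: Dict[str, List[str]] = {}
    for g in bacteria:
        genus_table.setdefault(g.genus, []).append(g.genome_id)
    estimates: List[AncestryEstimate] = []
    naive: List[AncestryEstimate] = []
    if scored and bacteria:
        sample_size = config.sample_size or len(archaea)
        scheme = DownsampleScheme(
            genus_table=genus_table,
            sample_size=sample_size,
            n_replicates=config.n_replicates,
            seed=config.seed,
        )
        estimates = estimate_proportions(scored, scheme, archaea, euk_genome_ids)
        naive_scheme = DownsampleScheme(
            genus_table=genus_table,
            sample_size=len(bacteria),
            n_replicates=1,
            seed=config.seed,
        )
        naive = estimate_proportions(scored, naive_scheme, archaea, euk_genome_ids)

    group_map = {
        g.genome_id: {"group": g.group, "plastid": g.plastid, "parasite": g.parasite}
        for g in genomes
        if g.domain == "eukaryote"
    }
    group_table = (
        group_summary(estimates, group_map)
        if estimates and any(not e.undefined for e in estimates)
        else pd.DataFrame()
    )

    # ---- annotation & reporting --------------------------------------------
    ref_seqs, ref_labels = make_annotation_reference(
        truth,
        genomes,
        np.random.default_rng(np.random.SeedSequence((config.seed, 7919))),
        identity_to_members=config.annotation_reference_identity,
    )
    category_table = pd.DataFrame()
    annotations = {}
    if config.run_annotation and ref_seqs and scored:
        reference = AnnotationReference(ref_seqs, ref_labels)
        annotations = annotate_epcs(
            scored,
            seq_lookup,
            reference,
            scoring,
            min_coverage=config.min_annotation_coverage,
        )
        category_table = category_origin_summary(annotations, scored)
    matrix_epcs = [e for e in epcs if e.origin in ("bacterial", "archaeal", "dual")]
    presence = (
        presence_absence_matrix(matrix_epcs, genomes)
        if matrix_epcs and config.run_presence_matrix
        else pd.DataFrame()
    )

    result = PipelineResult(
        config=config,
        genomes=genomes,
        truth=truth,
        families=families,
        epcs=epcs,
        estimates=estimates,
        naive_estimates=naive,
        group_table=group_table,
        category_table=category_table,
        presence_matrix=presence,
        manifest=manifest,
        dropped_clusters=dropped_log,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fam_rows = [
        (f.family_id, f.domain, m, g)
        for fams in result.families.values()
        for f in fams
        for m, g in zip(f.members, f.genomes)
    ]
    pd.DataFrame(fam_rows, columns=["family_id", "domain", "seq_id", "genome_id"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False
    )
    epc_rows = [
        (
            e.epc_id,
            e.euk_family.family_id,
            e.origin,
            ";".join(f.family_id for f in e.bacterial_families),
            ";".join(f.family_id for f in e.archaeal_families),
            ";".join(sorted(e.euk_genomes)),
        )
        for e in result.epcs
    ]
    pd.DataFrame(
        epc_rows,
        columns=["epc_id", "euk_family", "origin", "bacterial_families", "archaeal_families", "euk_genomes"],
    ).to_csv(outdir / "epcs.tsv", sep="\t", index=False)
    est_rows = [
        (
            e.genome_id,
            e.mean_bacterial,
            e.mean_archaeal,
            "" if e.p_bacterial is None else round(e.p_bacterial, 6),
            "" if e.p_archaeal is None else round(e.p_archaeal, 6),
            e.sd_bacterial,
        )
        for e in result.estimates
    ]
    pd.DataFrame(
        est_rows,
        columns=["genome_id", "mean_bacterial", "mean_archaeal", "p_bacterial", "p_archaeal", "sd_bacterial"],
    ).to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    if len(result.group_table):
        rounded = result.group_table.copy()
        rounded["p_archaeal"] = rounded["p_archaeal"].round(2)
        rounded["p_bacterial"] = rounded["p_bacterial"].round(2)
        rounded.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    if len(result.category_table):
        result.category_table.to_csv(outdir / "category_summary.tsv", sep="\t", index=False)
    if len(result.presence_matrix):
        result.presence_matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
    # exclusion log: dropped clusters and excluded EPCs, with reasons
    excl_rows = []
    for domain, clusters in result.dropped_clusters.items():
        reason = (
            "fewer_than_min_prok_family_size" if domain != "eukaryote" else "fewer_than_min_euk_species"
        )
        for c in clusters:
            excl_rows.append((domain, ";".join(sorted(c)), reason))
    for e in result.epcs:
        if e.origin in ("ambiguous", "dual", "excluded_by_recheck"):
            excl_rows.append(
                ("epc", e.epc_id, {"ambiguous": "multiple_prokaryote_clusters",
                                   "dual": "merged_dual_domain",
                                   "excluded_by_recheck": "other_domain_homolog_detected"}[e.origin])
            )
    pd.DataFrame(excl_rows, columns=["scope", "item", "reason"]).to_csv(
        outdir / "exclusions.tsv", sep="\t", index=False
    )
    (outdir / "manifest.json").write_text(json.dumps(result.manifest.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# survey-scale accounting (printed-ledger arithmetic)
# ---------------------------------------------------------------------------

def derived_survey_quantities(counts: Mapping[str, float]) -> Dict[str, float]:
    """Derive the survey's headline bookkeeping numbers from component counts.

    Expects the primitive counters (bacterial-only, archaeal-only and dual EPC
    counts, recheck exclusions, eukaryote-specific and ambiguous cluster
    counts, genome tallies and the overall bacterial proportion) and returns
    every derived quantity the accounting identities produce.
    """
    b = counts["n_bacterial_only"]
    a = counts["n_archaeal_only"]
    d = counts["n_dual"]
    excl = counts["n_recheck_excluded"]
    esc = counts["n_eukaryote_specific"]
    amb = counts["n_ambiguous"]
    out: Dict[str, float] = {}
    out["n_epc"] = b + a + d
    out["n_exclusive"] = b + a
    out["n_final"] = b + a - excl
    out["bacterial_archaeal_fold_excess"] = b / a
    out["n_eukaryote_clusters"] = esc + amb + out["n_epc"]
    out["epc_pct_of_eukaryote_clusters"] = 100.0 * out["n_epc"] / out["n_eukaryote_clusters"]
    out["dual_pct_of_epcs"] = 100.0 * d / out["n_epc"]
    if "p_bacterial_overall" in counts:
        p = counts["p_bacterial_overall"]
        out["bacterial_excess_pct"] = 100.0 * (p - (1.0 - p))
    if "n_bacteria" in counts and "n_archaea" in counts:
        out["bacteria_archaea_genome_fold"] = counts["n_bacteria"] / counts["n_archaea"]
    return out
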