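"""Per-genome bacterial/archaeal gene proportions via genus-stratified
downsampling.

Bacterial genome collections dwarf archaeal ones, so a eukaryote family is far
more likely to *detect* a bacterial partner than an archaeal one.  To equalize
detection sensitivity, bacterial genomes are repeatedly subsampled down to the
archaeal sample size, stratified by genus so each replicate mirrors the genus
composition of the full collection (proportional quotas, integerized by
largest remainder; genomes drawn uniformly without replacement within each
genus).  In every replicate, a bacterial EPC scores +1 for each eukaryote
genome in its presence set iff at least one sampled bacterial genome carries
the family; archaeal EPCs are scored against the full (replicate-independent)
archaeal set.  Each eukaryote genome counts at most once per EPC, so gene
duplications do not inflate the estimates.  Per-genome means over replicates
give the bacterial/archaeal counts, and their ratio the proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .epc import EPC, EXCLUSIVE_ORIGINS

__all__ = [
    "DownsampleScheme",
    "AncestryEstimate",
    "largest_remainder_quotas",
    "draw_bacterial_subsample",
    "score_replicate",
    "estimate_proportions",
    "group_summary",
    "size_correlation",
]


@dataclass(frozen=True)
class DownsampleScheme:
    """Replicated genus-stratified subsampling plan for bacterial genomes."""

    genus_table: Mapping[str, Sequence[str]]  # genus -> bacterial genome ids
    sample_size: int  # per replicate; the archaeal genome count in the survey
    n_replicates: int = 1000
    seed: int = 0
    mode: str = "stratified"  # or "uniform"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.sample_size <= 0:
            raise ValueError("sample size must be positive")
        if self.sample_size > self.population_size:
            raise ValueError("sample size exceeds bacterial population")
        if self.mode not in ("stratified", "uniform"):
            raise ValueError("mode must be 'stratified' or 'uniform'")

    @property
    def population_size(self) -> int:
        return sum(len(v) for v in self.genus_table.values())


@dataclass
class AncestryEstimate:
    """Mean bacterial/archaeal EPC counts and proportions for one genome."""

    genome_id: str
    mean_bacterial: float
    mean_archaeal: float
    sd_bacterial: float
    sd_archaeal: float

    @property
    def p_bacterial(self) -> Optional[float]:
        total = self.mean_bacterial + self.mean_archaeal
        return self.mean_bacterial / total if total > 0 else None

    @property
    def p_archaeal(self) -> Optional[float]:
        p = self.p_bacterial
        return None if p is None else 1.0 - p

    @property
    def undefined(self) -> bool:
        return self.mean_bacterial + self.mean_archaeal == 0


def largest_remainder_quotas(sizes: Sequence[int], sample_size: int) -> List[int]:
    """Proportional quotas integerized by the largest-remainder rule.

    Quota_g = sample_size * size_g / total, floored; remaining units go to the
    largest fractional remainders (ties to the earlier stratum).  Quotas are
    capped by stratum size; any capped surplus is reallocated to the remaining
    strata by the same rule.
    """
    sizes = list(sizes)
    total = sum(sizes)
    if sample_size > total:
        raise ValueError("sample size exceeds population")
    exact = [sample_size * s / total for s in sizes]
    quotas = [int(np.floor(q)) for q in exact]
    remainders = [q - f for q, f in zip(exact, quotas)]
    short = sample_size - sum(quotas)
    order = sorted(range(len(sizes)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        quotas[i] += 1
    # cap at stratum sizes and push surplus into strata with headroom
    surplus = 0
    for i, s in enumerate(sizes):
        if quotas[i] > s:
            surplus += quotas[i] - s
            quotas[i] = s
    while surplus > 0:
        headroom = [i for i in range(len(sizes)) if quotas[i] < sizes[i]]
        if not headroom:
            raise ValueError("cannot satisfy sample size")
        i = max(headroom, key=lambda i: (sizes[i] - quotas[i], -i))
        quotas[i] += 1
        surplus -= 1
    return quotas


def draw_bacterial_subsample(scheme: DownsampleScheme, replicate_index: int) -> Set[str]:
    """The bacterial genome set of one replicate; deterministic in
    (seed, replicate_index)."""
    rng = np.random.default_rng(np.random.SeedSequence((scheme.seed, replicate_index)))
    genera = sorted(scheme.genus_table)
    if scheme.mode == "uniform":
        pool = sorted(g for genus in genera for g in scheme.genus_table[genus])
        picked = rng.choice(len(pool), size=scheme.sample_size, replace=False)
        return {pool[i] for i in picked}
    sizes = [len(scheme.genus_table[g]) for g in genera]
    quotas = largest_remainder_quotas(sizes, scheme.sample_size)
    sample: Set[str] = set()
    for genus, quota in zip(genera, quotas):
        members = sorted(scheme.genus_table[genus])
        if quota == len(members):
            sample.update(members)
        elif quota > 0:
            picked = rng.choice(len(members), size=quota, replace=False)
            sample.update(members[i] for i in picked)
    return sample


def _split_epcs(epcs: Sequence[EPC]):
    bact, arch = [], []
    for e in epcs:
        if e.origin == "bacterial":
            bact.append(e)
        elif e.origin == "archaeal":
            arch.append(e)
        else:
            raise ValueError(
                f"EPC {e.epc_id} has origin '{e.origin}'; only exclusive EPCs may be scored"
            )
    return bact, arch


def score_replicate(
    epcs: Sequence[EPC],
    bacterial_sample: Set[str],
    archaeal_set: Set[str],
) -> Dict[str, Tuple[int, int]]:
    """Per-eukaryote-genome (bacterial, archaeal) counts for one replicate.

    A bacterial EPC contributes iff its prokaryotic presence set intersects
    the replicate's bacterial sample; an archaeal EPC iff it intersects the
    archaeal set.  Every eukaryote genome in the EPC's presence set then gains
    +1 in the matching counter — once per EPC, regardless of paralog count.
    """
    bact, arch = _split_epcs(epcs)
    counts: Dict[str, List[int]] = {}
    for e in bact:
        if e.prok_genomes & bacterial_sample:
            for g in e.euk_genomes:
                counts.setdefault(g, [0, 0])[0] += 1
    for e in arch:
        if e.prok_genomes & archaeal_set:
            for g in e.euk_genomes:
                counts.setdefault(g, [0, 0])[1] += 1
    return {g: (b, a) for g, (b, a) in counts.items()}


def estimate_proportions(
    epcs: Sequence[EPC],
    scheme: DownsampleScheme,
    archaeal_set: Set[str],
    eukaryote_genomes: Optional[Sequence[str]] = None,
) -> List[AncestryEstimate]:
    """Mean per-genome counts over all downsampling replicates.

    The proportion is the ratio of mean counts (robust to replicates with
    zero totals).  Archaeal counts are replicate-independent (the full
    archaeal set is always included) and are computed once.  Genomes with no
    scored EPC at all are reported with undefined proportions.
    """
    bact_epcs, arch_epcs = _split_epcs(epcs)
    if eukaryote_genomes is None:
        eukaryote_genomes = sorted(
            {g for e in epcs for g in e.euk_genomes}
        )
    genomes = list(eukaryote_genomes)
    gidx = {g: i for i, g in enumerate(genomes)}

    arch_counts = np.zeros(len(genomes))
    for e in arch_epcs:
        if e.prok_genomes & archaeal_set:
            for g in e.euk_genomes:
                arch_counts[gidx[g]] += 1

    # bacterial EPC x replicate detection, vectorized over replicates
    bact_mat = np.zeros((scheme.n_replicates, len(genomes)), dtype=np.int32)
    presence = [e.prok_genomes for e in bact_epcs]
    euk_lists = [[gidx[g] for g in e.euk_genomes] for e in bact_epcs]
    for r in range(scheme.n_replicates):
        sample = draw_bacterial_subsample(scheme, r)
        row = bact_mat[r]
        for pres, euks in zip(presence, euk_lists):
            if pres & sample:
                for gi in euks:
                    row[gi] += 1
    mean_b = bact_mat.mean(axis=0)
    sd_b = bact_mat.std(axis=0, ddof=0)
    out = []
    for g in genomes:
        i = gidx[g]
        out.append(
            AncestryEstimate(
                genome_id=g,
                mean_bacterial=float(mean_b[i]),
                mean_archaeal=float(arch_counts[i]),
                sd_bacterial=float(sd_b[i]),
                sd_archaeal=0.0,
            )
        )
    return out


def group_summary(
    estimates: Sequence[AncestryEstimate],
    group_map: Mapping[str, Mapping],
) -> pd.DataFrame:
    """Per-group unweighted means of per-genome proportions, plus composite
    rows (all eukaryotes; with plastids; without plastids; parasites).

    ``group_map`` maps genome_id to a mapping with keys ``group``, ``plastid``
    and ``parasite``.  Raises on unmapped genomes; groups with no genome with
    defined proportions are omitted.
    """
    rows = []
    for est in estimates:
        if est.genome_id not in group_map:
            raise KeyError(f"genome {est.genome_id} missing from group map")
        if est.undefined:
            continue
        info = group_map[est.genome_id]
        rows.append(
            {
                "genome_id": est.genome_id,
                "group": info["group"],
                "plastid": bool(info["plastid"]),
                "parasite": bool(info["parasite"]),
                "p_archaeal": est.p_archaeal,
                "p_bacterial": est.p_bacterial,
            }
        )
    if not rows:
        raise ValueError("no genomes with defined proportions")
    df = pd.DataFrame(rows)
    summaries = []

    def add(label, mask):
        sub = df[mask]
        if len(sub):
            summaries.append(
                {
                    "group": label,
                    "n_genomes": len(sub),
                    "p_archaeal": sub.p_archaeal.mean(),
                    "p_bacterial": sub.p_bacterial.mean(),
                }
            )

    add("All eukaryotes", df.index == df.index)
    add("All without plastids", ~df.plastid)
    add("All with plastids", df.plastid)
    for grp in sorted(df.group.unique()):
        add(grp, df.group == grp)
    add("Parasites", df.parasite)
    return pd.DataFrame(summaries)


def size_correlation(
    estimates: Sequence[AncestryEstimate],
    proteome_sizes: Mapping[str, int],
) -> Tuple[float, float]:
    """Squared Pearson correlations (archaeal, bacterial) between per-genome
    mean counts and proteome size."""
    ests = [e for e in estimates]
    if len(ests) < 3:
        raise ValueError("need at least three genomes")
    sizes = np.array([proteome_sizes[e.genome_id] for e in ests], dtype=float)
    if np.allclose(sizes, sizes[0]):
        raise ValueError("proteome sizes are constant")
    arch = np.array([e.mean_archaeal for e in ests])
    bact = np.array([e.mean_bacterial for e in ests])

    def r2(x):
        if np.allclose(x, x[0]):
            raise ValueError("count vector is constant")
        return float(stats.pearsonr(x, sizes).statistic ** 2)

    return r2(arch), r2(bact)
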