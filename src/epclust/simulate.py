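"""Synthetic multi-domain proteome generator with planted homology structure.

Generates bacterial, archaeal and eukaryotic "genomes" whose protein content
is organized into gene families of five planted categories:

* ``euk_specific`` — eukaryotes only,
* ``euk_bact``     — eukaryotes + bacteria (planted origin: bacterial),
* ``euk_arch``     — eukaryotes + archaea (planted origin: archaeal),
* ``euk_dual``     — eukaryotes + both prokaryotic domains (origin: dual),
* ``prok_only``    — prokaryotes only (alternately bacteria- or archaea-only).

Every family descends from a random ancestral sequence by substitution-only
evolution (no indels): a family root spawns per-domain ancestors, which spawn
the member sequences.  Per-edge retention probabilities are calibrated so the
*pairwise* identities land on the configured targets — within-domain pairs on
``within_domain_identity`` and cross-domain pairs on ``interdomain_identity``
(realized identities are within a few points of the target; the calibration
accounts for convergent substitutions).

Family presence per genome is an independent Bernoulli draw with a per-domain
probability; "parasite" eukaryote genomes lose bacteria-linked (``euk_bact``)
families at a multiplied loss rate, emulating reductive genome evolution in
intracellular parasites.  Bacterial genomes are organized into genera with a
configurable (typically skewed) size distribution; archaea carry no genus
structure because only the bacterial sample is ever downsampled.  Family-level
function labels are correlated with planted origin (metabolism with bacterial,
genetic-information processing with archaeal), emulating the functional
dichotomy of eukaryotic gene origins.

Identical seeds produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import AMINO_ACIDS

CATEGORIES = ("euk_specific", "euk_bact", "euk_arch", "euk_dual", "prok_only")
FUNCTION_CATEGORIES = (
    "metabolism",
    "information",
    "environmental",
    "cellular",
    "organismal",
    "other",
)
EUK_GROUPS = ("Archaeplastida", "SAR", "Hacrobia", "Opisthokonts", "Excavata", "Mycetozoa")
PLASTID_GROUPS = frozenset({"Archaeplastida", "SAR", "Hacrobia"})

__all__ = [
    "CATEGORIES",
    "FUNCTION_CATEGORIES",
    "EUK_GROUPS",
    "PLASTID_GROUPS",
    "GenomeRecord",
    "SimulationConfig",
    "TruthTable",
    "mutate_sequence",
    "random_protein",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "make_annotation_reference",
]


@dataclass
class GenomeRecord:
    """One proteome plus its taxonomy and flags."""

    genome_id: str
    domain: str  # bacteria | archaea | eukaryote
    genus: str
    group: str  # eukaryote supergroup label; "" for prokaryotes
    plastid: bool
    parasite: bool
    proteins: Dict[str, str] = field(default_factory=dict)  # seq_id -> sequence

    @property
    def proteome_size(self) -> int:
        return len(self.proteins)


@dataclass
class SimulationConfig:
    n_bacteria: int = 30
    n_archaea: int = 12
    n_eukaryotes: int = 8
    genus_sizes: Sequence[int] = (14, 8, 4, 3, 1)
    n_euk_specific: int = 4
    n_euk_bact: int = 60
    n_euk_arch: int = 40
    n_euk_dual: int = 2
    n_prok_only: int = 3
    within_domain_identity: float = 80.0  # target % identity, same-domain pairs
    interdomain_identity: float = 45.0  # target % identity, cross-domain pairs
    presence_prob: Mapping[str, float] = field(
        default_factory=lambda: {"bacteria": 0.7, "archaea": 0.7, "eukaryote": 0.7}
    )
    parasite_ids: Sequence[str] = ()
    parasite_loss_multiplier: float = 2.0
    p_metabolism_given_bact: float = 0.8
    p_information_given_arch: float = 0.8
    seq_length_range: Tuple[int, int] = (120, 200)
    seed: int = 0

    @property
    def planted_bacterial_fraction(self) -> float:
        """euk_bact / (euk_bact + euk_arch) — the truth the pipeline recovers."""
        total = self.n_euk_bact + self.n_euk_arch
        if total == 0:
            raise ValueError("no bacteria- or archaea-linked families configured")
        return self.n_euk_bact / total

    def validate(self) -> None:
        counts = (
            self.n_bacteria,
            self.n_archaea,
            self.n_eukaryotes,
            self.n_euk_specific,
            self.n_euk_bact,
            self.n_euk_arch,
            self.n_euk_dual,
            self.n_prok_only,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if sum(self.genus_sizes) != self.n_bacteria:
            raise ValueError(
                f"genus sizes sum to {sum(self.genus_sizes)}, expected n_bacteria={self.n_bacteria}"
            )
        for dom, p in self.presence_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"presence_prob[{dom}] outside [0, 1]")
        n_euk_fams = self.n_euk_specific + self.n_euk_bact + self.n_euk_arch + self.n_euk_dual
        if self.n_eukaryotes == 0 and n_euk_fams > 0:
            raise ValueError("eukaryote families configured but no eukaryote genomes")
        if not self.within_domain_identity > self.interdomain_identity:
            raise ValueError("within-domain identity must exceed interdomain identity")
        if self.interdomain_identity <= 100.0 / len(AMINO_ACIDS):
            raise ValueError("interdomain identity must exceed random background")
        lo, hi = self.seq_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid sequence length range")


@dataclass
class TruthTable:
    """Planted ground truth: family -> category/members/function/origin."""

    category: Dict[str, str] = field(default_factory=dict)
    members: Dict[str, Dict[str, List[str]]] = field(default_factory=dict)  # fam -> genome -> seq ids
    function: Dict[str, str] = field(default_factory=dict)  # fam -> function category
    origin: Dict[str, str] = field(default_factory=dict)  # bacterial|archaeal|dual|none

    def family_of(self, seq_id: str) -> str:
        return self._seq_index[seq_id]

    def finalize(self) -> None:
        self._seq_index: Dict[str, str] = {}
        for fam, per_genome in self.members.items():
            for seq_ids in per_genome.values():
                for sid in seq_ids:
                    if sid in self._seq_index:
                        raise ValueError(f"sequence {sid} planted in two families")
                    self._seq_index[sid] = fam

    def category_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {c: 0 for c in CATEGORIES}
        for cat in self.category.values():
            out[cat] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in sorted(self.category):
            for genome in sorted(self.members[fam]):
                for sid in self.members[fam][genome]:
                    rows.append(
                        (fam, self.category[fam], self.origin[fam], self.function[fam], genome, sid)
                    )
        return pd.DataFrame(
            rows, columns=["family_id", "category", "origin", "function", "genome_id", "seq_id"]
        )


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def random_protein(length: int, rng: np.random.Generator) -> str:
    """Ancestral sequence with uniform residue frequencies (keeps the random
    background identity far below the clustering cutoffs)."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_sequence(ancestor: str, target_identity: float, seed) -> str:
    """Substitution-only descendant of ``ancestor``.

    Each position is retained with probability ``target_identity / 100``;
    mutated positions are resampled uniformly from the 19 other residues, so
    the expected fraction of unchanged positions equals the target.  A target
    of 100 returns the ancestor unchanged; a target of 0 resamples every
    position.  ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if not ancestor:
        raise ValueError("empty ancestor")
    if not 0.0 <= target_identity <= 100.0:
        raise ValueError("target identity must be in [0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_keep = target_identity / 100.0
    keep = rng.random(len(ancestor)) < p_keep
    out = list(ancestor)
    alphabet = AMINO_ACIDS
    for i in np.nonzero(~keep)[0]:
        choices = alphabet.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _edge_retentions(within_id: float, inter_id: float) -> Tuple[float, float]:
    """Per-edge retention probabilities (root->domain, domain->member).

    Pairwise identity between two tips whose paths retain with probabilities
    p and q is approximately p*q + (1-p)(1-q)/19 (convergent substitutions).
    Solving within = pm^2 + (1-pm)^2/19 for the member edge and pushing the
    remainder onto the root->domain edge keeps both targets within a couple of
    points, well inside the documented +-10-point band.
    """
    tw = within_id / 100.0
    # solve pm^2 + (1-pm)^2/19 = tw  (quadratic in pm)
    a = 1.0 + 1.0 / 19.0
    b = -2.0 / 19.0
    c = 1.0 / 19.0 - tw
    pm = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
    ti = inter_id / 100.0
    # cross-domain path retention: (pm * pd)^2 ~ ti  (ignore small convergence)
    pd_ = math.sqrt(max(ti, 1e-9)) / pm
    pd_ = min(max(pd_, 0.0), 1.0)
    return pm, pd_


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _family_domains(cat: str, flip_prok_only: bool) -> List[str]:
    if cat == "euk_specific":
        return ["eukaryote"]
    if cat == "euk_bact":
        return ["eukaryote", "bacteria"]
    if cat == "euk_arch":
        return ["eukaryote", "archaea"]
    if cat == "euk_dual":
        return ["eukaryote", "bacteria", "archaea"]
    return ["bacteria"] if flip_prok_only else ["archaea"]


_ORIGIN = {
    "euk_specific": "none",
    "euk_bact": "bacterial",
    "euk_arch": "archaeal",
    "euk_dual": "dual",
    "prok_only": "none",
}


def simulate_dataset(config: SimulationConfig) -> Tuple[List[GenomeRecord], TruthTable]:
    """Generate one proteome per genome plus the planted truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pm, pd_ = _edge_retentions(config.within_domain_identity, config.interdomain_identity)

    genomes: List[GenomeRecord] = []
    genus_names = [f"genus{g + 1:02d}" for g in range(len(config.genus_sizes))]
    k = 0
    for gname, size in zip(genus_names, config.genus_sizes):
        for _ in range(size):
            gid = f"bact{k + 1:04d}"
            genomes.append(GenomeRecord(gid, "bacteria", gname, "", False, False))
            k += 1
    for i in range(config.n_archaea):
        gid = f"arch{i + 1:04d}"
        genomes.append(GenomeRecord(gid, "archaea", gid, "", False, False))
    parasites = set(config.parasite_ids)
    for i in range(config.n_eukaryotes):
        gid = f"euk{i + 1:04d}"
        group = EUK_GROUPS[i % len(EUK_GROUPS)]
        genomes.append(
            GenomeRecord(gid, "eukaryote", gid, group, group in PLASTID_GROUPS, gid in parasites)
        )
    unknown = parasites - {g.genome_id for g in genomes}
    if unknown:
        raise ValueError(f"parasite ids not among eukaryote genomes: {sorted(unknown)}")
    by_domain: Dict[str, List[GenomeRecord]] = {"bacteria": [], "archaea": [], "eukaryote": []}
    for g in genomes:
        by_domain[g.domain].append(g)

    fam_plan: List[Tuple[str, str]] = []
    counts = {
        "euk_specific": config.n_euk_specific,
        "euk_bact": config.n_euk_bact,
        "euk_arch": config.n_euk_arch,
        "euk_dual": config.n_euk_dual,
        "prok_only": config.n_prok_only,
    }
    fid = 0
    for cat in CATEGORIES:
        for _ in range(counts[cat]):
            fid += 1
            fam_plan.append((f"fam{fid:05d}", cat))

    truth = TruthTable()
    serial = {g.genome_id: 0 for g in genomes}
    lo, hi = config.seq_length_range
    prok_flip = True
    for fam_id, cat in fam_plan:
        if cat == "prok_only":
            domains = _family_domains(cat, prok_flip)
            prok_flip = not prok_flip
        else:
            domains = _family_domains(cat, False)
        length = int(rng.integers(lo, hi + 1))
        root = random_protein(length, rng)
        truth.category[fam_id] = cat
        truth.origin[fam_id] = _ORIGIN[cat]
        truth.members[fam_id] = {}
        # function label correlated with planted origin
        u = rng.random()
        if cat == "euk_bact" and u < config.p_metabolism_given_bact:
            func = "metabolism"
        elif cat == "euk_arch" and u < config.p_information_given_arch:
            func = "information"
        else:
            others = [c for c in FUNCTION_CATEGORIES]
            if cat == "euk_bact":
                others.remove("metabolism")
            elif cat == "euk_arch":
                others.remove("information")
            func = others[rng.integers(len(others))]
        truth.function[fam_id] = func

        for domain in domains:
            dom_anc = mutate_sequence(root, 100.0 * pd_, rng)
            presence = config.presence_prob.get(domain, 0.7)
            for genome in by_domain[domain]:
                p = presence
                if domain == "eukaryote" and genome.parasite and cat in ("euk_bact", "euk_dual"):
                    p = max(0.0, 1.0 - (1.0 - presence) * config.parasite_loss_multiplier)
                if rng.random() >= p:
                    continue
                serial[genome.genome_id] += 1
                sid = f"{genome.genome_id}_p{serial[genome.genome_id]:05d}"
                genome.proteins[sid] = mutate_sequence(dom_anc, 100.0 * pm, rng)
                truth.members[fam_id].setdefault(genome.genome_id, []).append(sid)

    truth.finalize()
    return genomes, truth


# ---------------------------------------------------------------------------
# on-disk round trip (FASTA per genome + metadata/truth TSV sidecars)
# ---------------------------------------------------------------------------

def write_dataset(genomes: Sequence[GenomeRecord], truth: TruthTable, outdir) -> None:
    """FASTA per genome (plain seq ids; family only in the truth sidecar),
    metadata.tsv and truth.tsv."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    outdir = Path(outdir)
    fasta_dir = outdir / "proteomes"
    fasta_dir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        records = [
            SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sorted(g.proteins.items())
        ]
        SeqIO.write(records, fasta_dir / f"{g.genome_id}.faa", "fasta")
    meta = pd.DataFrame(
        [
            (g.genome_id, g.domain, g.genus, g.group, int(g.plastid), int(g.parasite))
            for g in genomes
        ],
        columns=["genome_id", "domain", "genus", "group", "plastid", "parasite"],
    )
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_dataset(outdir) -> Tuple[List[GenomeRecord], TruthTable]:
    from Bio import SeqIO

    outdir = Path(outdir)
    meta = pd.read_csv(outdir / "metadata.tsv", sep="\t", keep_default_na=False)
    genomes = []
    for _, row in meta.iterrows():
        g = GenomeRecord(
            row.genome_id,
            row.domain,
            str(row.genus),
            str(row.group),
            bool(row.plastid),
            bool(row.parasite),
        )
        path = outdir / "proteomes" / f"{g.genome_id}.faa"
        for rec in SeqIO.parse(str(path), "fasta"):
            g.proteins[rec.id] = str(rec.seq)
        genomes.append(g)
    truth = TruthTable()
    tf = pd.read_csv(outdir / "truth.tsv", sep="\t")
    for _, row in tf.iterrows():
        fam = row.family_id
        truth.category[fam] = row.category
        truth.origin[fam] = row.origin
        truth.function[fam] = row["function"]
        truth.members.setdefault(fam, {}).setdefault(row.genome_id, []).append(row.seq_id)
    truth.finalize()
    return genomes, truth


def make_annotation_reference(
    truth: TruthTable,
    genomes: Sequence[GenomeRecord],
    rng_or_seed,
    identity_to_members: float = 60.0,
    labeled_fraction: float = 1.0,
):
    """Synthetic labeled reference proteins for the annotation stage.

    One reference entry per (labeled) family, derived from an arbitrary family
    member at the requested identity so best-hit assignment at the E-value and
    coverage gates succeeds for true members.  Returns ``(sequences, labels)``
    where labels maps ``ref_id -> (function_id, category)``.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    seq_lookup: Dict[str, str] = {}
    for g in genomes:
        seq_lookup.update(g.proteins)
    sequences: Dict[str, str] = {}
    labels: Dict[str, Tuple[str, str]] = {}
    for i, fam in enumerate(sorted(truth.category)):
        if labeled_fraction < 1.0 and rng.random() >= labeled_fraction:
            continue
        member_ids = [sid for per_g in truth.members[fam].values() for sid in per_g]
        if not member_ids:
            continue
        template = seq_lookup[sorted(member_ids)[0]]
        ref_id = f"ref{i + 1:05d}"
        sequences[ref_id] = mutate_sequence(template, identity_to_members, rng)
        labels[ref_id] = (f"K{i + 1:05d}", truth.function[fam])
    return sequences, labels
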