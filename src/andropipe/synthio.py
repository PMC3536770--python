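"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of (config, seed) and returns ground truth
alongside the data, so each downstream stage is verifiable without the
deposited study data:

* :func:`simulate_experiment` — per-spot clone signal S, vector-oligo signal
  V, per-array background, the study's group structure (control n=14, T1 d7
  n=5, T2 d7 n=4, T2 d14 n=5, 11KT d7 n=7), and planted multiplicative
  treatment effects on a subset of clones.
* :func:`simulate_dev_atlas` — clone assignments to developmental clusters
  A-I with archetypal stage/germ-fraction profiles.
* :func:`simulate_genome` — a toy genome with TSS table, per-base
  conservation track and planted response-element instances.
* :func:`simulate_go` — a rooted ontology DAG with annotations and one
  planted enriched term.

Signals are log-normal: radioactive spot intensities are positive and
right-skewed, and a multiplicative model is the simplest one consistent with
the log2 analysis downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .footprint import PWM, reverse_complement
from .meta import ATLAS_LABELS, DevAtlas
from .normalize import GROUP_NAMES, SignalMatrix

#: the study's group sizes
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "control": 14,
    "T1d7": 5,
    "T2d7": 4,
    "T2d14": 5,
    "KTd7": 7,
}

#: response patterns: per-group exponent applied to the clone's log effect,
#: with draw probabilities roughly matching the observed cluster proportions
RESPONSE_PATTERNS: dict[str, dict[str, float]] = {
    "down": {"T1d7": -0.7, "T2d7": -1.0, "T2d14": -1.0, "KTd7": -0.8},
    "up_d7": {"T1d7": 0.5, "T2d7": 1.0, "T2d14": 0.4, "KTd7": 0.75},
    "up_d14": {"T1d7": 0.0, "T2d7": 0.3, "T2d14": 1.0, "KTd7": 0.3},
    "down_d7_up_d14": {"T1d7": -0.5, "T2d7": -1.0, "T2d14": 1.0, "KTd7": -0.5},
}
RESPONSE_PATTERN_PROBS = (0.21, 0.42, 0.25, 0.12)

#: pattern -> the semantic response-cluster label it should land in
PATTERN_TO_LABEL = {"down": 1, "up_d7": 2, "up_d14": 3, "down_d7_up_d14": 4}


@dataclass
class SyntheticTruth:
    """Ground-truth records for one synthetic dataset."""

    seed: int
    de_clones: dict[str, dict] = field(default_factory=dict)
    # clone -> {"effect": fold>1, "direction": +/-1, "pattern": str,
    #           "multipliers": {group: x}}
    motif_instances: list[dict] = field(default_factory=list)
    # {"gene", "matrix", "contig", "start", "end", "strand", "rel_start",
    #  "conservation"}
    enriched_terms: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# expression experiment
# ---------------------------------------------------------------------------


def simulate_experiment(
    n_clones: int = 8000,
    group_sizes: Mapping[str, int] | None = None,
    frac_de: float = 0.05,
    effect_range: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
    sigma_noise: float = 0.3,
    frac_low_v: float = 0.05,
    p_up: float = 0.5,
) -> tuple[SignalMatrix, SyntheticTruth]:
    """Simulate the androgen-supplementation array experiment.

    Clone baseline abundances and vector signals are log-normal; the spot
    signal is S = abundance * V * multiplicative noise (ln-scale sigma
    ``sigma_noise``).  Planted responsive clones have their group means
    multiplied by a per-clone effect (uniform in ``effect_range``, direction
    via ``p_up``) shaped by one of the four response patterns.  A fraction
    ``frac_low_v`` of clones receives a vector signal below 3x background in
    most arrays, to exercise the non-informative filter.
    """
    if n_clones < 10:
        raise InvalidConfigError("n_clones must be >= 10")
    group_sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    unknown = set(group_sizes) - set(GROUP_NAMES)
    if unknown:
        raise InvalidConfigError(f"unknown group names: {sorted(unknown)}")
    if "control" not in group_sizes:
        raise InvalidConfigError("group_sizes must include 'control'")
    if any(int(n) < 2 for n in group_sizes.values()):
        raise InvalidConfigError("all group sizes must be >= 2")
    if not 0.0 <= frac_de <= 0.5:
        raise InvalidConfigError("frac_de must be in [0, 0.5]")
    lo, hi = effect_range
    if not (lo > 1.0 and hi >= lo):
        raise InvalidConfigError("effect_range must satisfy 1 < lo <= hi")

    rng = np.random.default_rng(seed)
    clones = [f"clone{i:05d}" for i in range(n_clones)]
    samples, groups = [], []
    for g in GROUP_NAMES:
        for i in range(group_sizes.get(g, 0)):
            samples.append(f"{g}_{i + 1:02d}")
            groups.append(g)
    n_samples = len(samples)
    groups = pd.Series(groups, index=samples, name="group")

    abundance = rng.lognormal(mean=6.0, sigma=1.0, size=n_clones)
    B = pd.Series(rng.lognormal(mean=np.log(30.0), sigma=0.2, size=n_samples),
                  index=samples, name="background")
    n_de = int(round(frac_de * n_clones))
    de_idx = np.sort(rng.choice(n_clones, size=n_de, replace=False)) if n_de else np.empty(0, int)

    # well-spotted clones sit comfortably above 3x background; only the
    # dedicated frac_low_v subset exercises the non-informative filter
    v_clone = rng.lognormal(mean=np.log(30.0) + 3.0, sigma=0.5, size=n_clones)
    n_low = int(round(frac_low_v * n_clones))
    # planted responsive clones are kept well-measured: the study's responsive
    # set was identified among accurately measured cDNAs
    low_pool = np.setdiff1d(np.arange(n_clones), de_idx)
    low_idx = rng.choice(low_pool, size=min(n_low, len(low_pool)), replace=False)
    v_clone[low_idx] = float(B.median()) * rng.uniform(0.5, 2.0, size=len(low_idx))
    V = v_clone[:, None] * rng.lognormal(mean=0.0, sigma=0.25, size=(n_clones, n_samples))

    truth = SyntheticTruth(seed=seed)
    log_mult = np.zeros((n_clones, n_samples))
    if n_de:
        patterns = rng.choice(list(RESPONSE_PATTERNS), size=n_de, p=RESPONSE_PATTERN_PROBS)
        effects = rng.uniform(lo, hi, size=n_de)
        directions = np.where(rng.random(n_de) < p_up, 1, -1)
        group_arr = groups.to_numpy()
        for idx, pat, eff, direction in zip(de_idx, patterns, effects, directions):
            multipliers = {}
            for g, expo in RESPONSE_PATTERNS[pat].items():
                mult = float(eff ** (direction * expo))
                multipliers[g] = mult
                log_mult[idx, group_arr == g] = np.log(mult)
            truth.de_clones[clones[idx]] = {
                "effect": float(eff),
                "direction": int(direction),
                "pattern": str(pat),
                "multipliers": multipliers,
            }

    noise = rng.lognormal(mean=0.0, sigma=sigma_noise, size=(n_clones, n_samples))
    S = abundance[:, None] * np.exp(log_mult) * V * noise
    sig = SignalMatrix(
        S=pd.DataFrame(S, index=clones, columns=samples),
        V=pd.DataFrame(V, index=clones, columns=samples),
        B=B,
        groups=groups,
    )
    return sig, truth


# ---------------------------------------------------------------------------
# developmental atlas
# ---------------------------------------------------------------------------

ATLAS_STAGES = ("I", "IIa", "IIb", "IIIb", "V", "VIII", "Sg", "Sc", "St")

#: archetypal stage/germ-fraction profiles (arbitrary log2-like units)
DEFAULT_ATLAS_ARCHETYPES: dict[str, tuple[float, ...]] = {
    # stages:            I    IIa  IIb  IIIb V    VIII Sg   Sc   St
    "A": (0.5, 0.6, 0.7, 0.9, 1.1, 1.6, 0.1, 0.1, 0.1),  # somatic, high late
    "B": (1.4, 1.3, 1.2, 1.0, 0.7, 0.2, 0.1, 0.1, 0.1),  # somatic, low in VIII
    "C": (0.3, 0.4, 0.5, 0.8, 1.2, 1.8, 0.1, 0.1, 0.1),  # somatic, very high VIII
    "D": (1.0, 1.1, 1.0, 0.8, 0.6, 0.4, 1.2, 0.3, 0.2),  # somatic + spermatogonia
    "E": (1.6, 1.4, 1.2, 0.6, 0.3, 0.1, 1.7, 0.3, 0.2),  # type A spermatogonia
    "F": (1.0, 1.5, 1.6, 0.8, 0.4, 0.1, 1.6, 0.5, 0.2),  # type B spermatogonia
    "G": (0.5, 0.8, 1.0, 1.2, 1.2, 0.4, 1.0, 1.1, 1.0),  # germline, broad
    "H": (0.1, 0.2, 0.4, 1.5, 1.7, 0.5, 0.3, 1.8, 1.6),  # meiotic/post-meiotic
    "I": (0.2, 0.2, 0.2, 0.3, 0.3, 0.2, 1.3, 1.4, 1.5),  # isolated germ cells only
}


def simulate_dev_atlas(
    clone_ids: Sequence[str],
    cluster_shapes: Mapping[str, Sequence[float]] | None = None,
    seed: int = 0,
    p_labeled: float = 0.7,
    noise_sd: float = 0.1,
) -> DevAtlas:
    """Assign clones to developmental clusters and draw archetype profiles."""
    shapes = dict(DEFAULT_ATLAS_ARCHETYPES if cluster_shapes is None else cluster_shapes)
    bad = set(shapes) - set(ATLAS_LABELS)
    if bad:
        raise InvalidConfigError(f"unknown atlas labels: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    labels: dict[str, str] = {}
    profiles: dict[str, np.ndarray] = {}
    label_pool = sorted(shapes)
    for clone in clone_ids:
        if rng.random() > p_labeled:
            continue
        label = label_pool[rng.integers(len(label_pool))]
        labels[clone] = label
        profiles[clone] = np.asarray(shapes[label], dtype=float) + rng.normal(
            0.0, noise_sd, size=len(ATLAS_STAGES)
        )
    prof = (
        pd.DataFrame.from_dict(profiles, orient="index", columns=list(ATLAS_STAGES))
        if profiles
        else pd.DataFrame(columns=list(ATLAS_STAGES))
    )
    return DevAtlas(
        labels=pd.Series(labels, dtype="object", name="atlas"),
        profiles=prof,
        stages=ATLAS_STAGES,
    )


# ---------------------------------------------------------------------------
# toy genome with planted motifs
# ---------------------------------------------------------------------------


def synthetic_matrices(seed: int = 0, dominant: float = 0.85) -> list[PWM]:
    """Synthetic stand-ins for the validated steroid-response matrices.

    The study's TRANSFAC matrices are proprietary, so androgen-response
    matrices are built here around the canonical AR-dimer inverted repeat
    AGAACAnnnTGTTCT (and an ERE-like palindrome) with a configurable dominant
    base frequency.  Ids are clearly synthetic.
    """
    consensi = {
        "AREsyn1": "AGAACAGCATGTTCT",
        "AREsyn2": "GGTACAGGATGTTCT",
        "AREsyn3": "AGAACATCCTGTACC",
        "AREsyn4": "AGTACGTGATGTTCT",
        "AREsyn5": "GGAACATTGTGTTCT",
        "EREsyn1": "AGGTCACAGTGACCT",
    }
    rng = np.random.default_rng(seed)
    rest = (1.0 - dominant) / 3.0
    pwms = []
    for mid, cons in consensi.items():
        freqs = np.full((len(cons), 4), rest)
        for i, base in enumerate(cons):
            freqs[i, "ACGT".index(base)] = dominant
        # jitter keeps matrices distinct without moving the consensus
        jitter = rng.uniform(0.0, 0.02, size=freqs.shape)
        freqs = freqs + jitter
        freqs /= freqs.sum(axis=1, keepdims=True)
        counts = np.round(freqs * 100, 4)
        pwms.append(PWM(id=mid, freqs=counts / counts.sum(axis=1, keepdims=True), counts=counts))
    return pwms


@dataclass
class PlantedMotif:
    """Instruction to plant a matrix consensus in one gene's promoter."""

    gene_index: int
    matrix_id: str
    rel_start: int  # TSS-relative, gene orientation
    conservation: float = 0.95


def simulate_genome(
    n_genes: int = 10,
    promoter_span: tuple[int, int] = (-10000, 2000),
    planted_motifs: Sequence[PlantedMotif] = (),
    seed: int = 0,
    matrices: Sequence[PWM] | None = None,
    background_conservation: tuple[float, float] = (0.05, 0.3),
    planted_conservation_default: float = 0.95,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, np.ndarray], SyntheticTruth]:
    """Toy genome: one contig per gene, TSS table, conservation, planted motifs.

    Background sequence is i.i.d. uniform over ACGT; planted instances are the
    exact consensus of a named matrix at recorded TSS-relative offsets (minus
    strand genes get the reverse complement in genomic coordinates).  The
    conservation track is low everywhere except over planted instances.
    Returns (contig->sequence, BED6-style TSS table, contig->per-base scores,
    truth).
    """
    if matrices is None:
        matrices = synthetic_matrices(seed=0)
    by_id = {m.id: m for m in matrices}
    lo, hi = promoter_span
    if not (lo < 0 <= hi):
        raise InvalidConfigError("promoter_span must bracket the TSS")
    span = hi - lo
    margin = 100
    contig_len = span + 2 * margin

    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    track: dict[str, np.ndarray] = {}
    rows = []
    strands = ["+" if i % 2 == 0 else "-" for i in range(n_genes)]
    for i in range(n_genes):
        contig = f"ctg{i:03d}"
        seq = "".join(rng.choice(list("ACGT"), size=contig_len))
        genome[contig] = seq
        base = rng.uniform(*background_conservation, size=contig_len)
        track[contig] = base
        # place the TSS so that the full window fits inside the contig
        tss = (-lo + margin) if strands[i] == "+" else (hi - 1 + margin)
        rows.append(
            {"chrom": contig, "start": tss, "end": tss + 1,
             "name": f"gene{i:03d}", "score": 0, "strand": strands[i]}
        )
    tss_table = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    truth = SyntheticTruth(seed=seed)
    for plant in planted_motifs:
        if plant.matrix_id not in by_id:
            raise InvalidConfigError(f"unknown matrix id {plant.matrix_id!r}")
        m = by_id[plant.matrix_id]
        if m.length > span:
            raise InvalidConfigError(f"motif {m.id} longer than the promoter window")
        if not (lo <= plant.rel_start and plant.rel_start + m.length <= hi):
            raise InvalidConfigError(
                f"planted motif at {plant.rel_start:+d} does not fit in the window"
            )
        row = tss_table.iloc[plant.gene_index]
        contig, tss, strand = row["chrom"], int(row["start"]), row["strand"]
        cons = m.consensus()
        if strand == "+":
            start = tss + plant.rel_start
            insert = cons
        else:
            start = tss - plant.rel_start - m.length + 1
            insert = reverse_complement(cons)
        end = start + m.length
        seq = genome[contig]
        genome[contig] = seq[:start] + insert + seq[end:]
        track[contig][start:end] = plant.conservation or planted_conservation_default
        truth.motif_instances.append(
            {
                "gene": row["name"],
                "matrix": m.id,
                "contig": contig,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "rel_start": int(plant.rel_start),
                "conservation": float(plant.conservation),
            }
        )
    return genome, tss_table, track, truth


# ---------------------------------------------------------------------------
# toy ontology
# ---------------------------------------------------------------------------


def simulate_go(
    n_terms: int,
    genes: Sequence[str],
    planted_term_size: int,
    seed: int = 0,
    planted_genes: Sequence[str] | None = None,
    mean_term_size: float = 8.0,
    n_cross_links: int = 0,
) -> tuple[nx.DiGraph, dict[str, set], str]:
    """Rooted ontology tree (plus optional cross-links) with annotations.

    One designated term's gene set is drawn to overlap ``planted_genes``
    heavily (all of them, topped up with random genes if needed).  Returns
    (dag with edges parent->child, term->genes, planted term id).
    """
    genes = list(genes)
    if n_terms < 1:
        raise InvalidConfigError("n_terms must be >= 1")
    if planted_term_size > len(genes):
        raise InvalidConfigError("planted_term_size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    dag = nx.DiGraph()
    dag.add_node(terms[0])
    for i in range(1, n_terms):
        parent = terms[rng.integers(i)]
        dag.add_edge(parent, terms[i])
    for _ in range(n_cross_links):
        if n_terms < 3:
            break
        a, b = sorted(rng.choice(n_terms, size=2, replace=False))
        dag.add_edge(terms[a], terms[b])  # low index -> high index keeps it acyclic
    if not nx.is_directed_acyclic_graph(dag):
        raise InvalidConfigError("cross-links introduced a cycle")

    annotations: dict[str, set] = {}
    for t in terms[1:]:
        size = min(len(genes), max(1, int(rng.poisson(mean_term_size))))
        annotations[t] = set(rng.choice(genes, size=size, replace=False))
    planted_term = terms[-1] if n_terms > 1 else terms[0]
    chosen = list(planted_genes or [])[:planted_term_size]
    pool = [g for g in genes if g not in chosen]
    extra = planted_term_size - len(chosen)
    if extra > 0:
        chosen += list(rng.choice(pool, size=extra, replace=False))
    annotations[planted_term] = set(chosen)
    return dag, annotations, planted_term
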