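"""Cross-tabulation against the spermatogenesis developmental atlas.

The atlas assigns clones to nine developmental clusters A-I derived from a
testis maturation time course (stages I-VIII) plus isolated germ-cell
fractions.  A-D are somatic expression clusters, E-I germline (E/F
spermatogonial, H meiotic/post-meiotic).  Crossing the four androgen-response
clusters with these labels separates somatic from germline responses and
quantifies the germline shift toward meiotic profiles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

ATLAS_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H", "I")
SOMATIC_LABELS = frozenset("ABCD")
GERMLINE_LABELS = frozenset("EFGHI")
SPERMATOGONIAL_LABELS = frozenset("EF")
MEIOTIC_LABELS = frozenset("H")
ANDROGEN_CLUSTERS = (1, 2, 3, 4)


@dataclass
class DevAtlas:
    """Clone -> developmental cluster mapping with optional stage profiles."""

    labels: pd.Series  # clone -> label in A..I (clones absent = not dev-regulated)
    profiles: pd.DataFrame | None = None  # clone x (stages + germ fractions)
    stages: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(ATLAS_LABELS)
        if bad:
            raise InvalidInputError(f"unknown atlas labels: {sorted(bad)}")


def classify_compartment(label: str) -> tuple[str, str | None]:
    """Map an atlas label to (compartment, sub-role).

    A-D -> somatic; E-I -> germline with sub-role spermatogonial (E, F) or
    meiotic (H).
    """
    if label in SOMATIC_LABELS:
        return "somatic", None
    if label in GERMLINE_LABELS:
        if label in SPERMATOGONIAL_LABELS:
            return "germline", "spermatogonial"
        if label in MEIOTIC_LABELS:
            return "germline", "meiotic"
        return "germline", None
    raise InvalidInputError(f"unknown atlas label {label!r}")


@dataclass
class CrossTab:
    """9x4 count table of atlas label x androgen cluster, with margins."""

    table: pd.DataFrame  # rows A..I, columns 1..4
    row_margins: pd.Series
    col_margins: pd.Series
    n_both: int  # clones carrying both labels


def cross_tabulate(androgen_clusters: pd.Series, atlas: DevAtlas) -> CrossTab:
    """Count clones per (atlas label, androgen cluster) cell.

    Clones lacking either label are excluded; the cell sum therefore equals
    the number of clones present in both maps.
    """
    androgen_clusters = pd.Series(androgen_clusters)
    common = androgen_clusters.index.intersection(atlas.labels.index)
    table = (
        pd.crosstab(atlas.labels.loc[common], androgen_clusters.loc[common])
        .reindex(index=list(ATLAS_LABELS), columns=list(ANDROGEN_CLUSTERS), fill_value=0)
        .astype(int)
    )
    table.index.name = "atlas"
    table.columns.name = "cluster"
    return CrossTab(
        table=table,
        row_margins=table.sum(axis=1),
        col_margins=table.sum(axis=0),
        n_both=int(table.to_numpy().sum()),
    )


def compartment_counts(tab: CrossTab) -> dict[str, int]:
    """Somatic vs germline totals over the cross-tab (a partition)."""
    somatic = int(tab.table.loc[list(sorted(SOMATIC_LABELS))].to_numpy().sum())
    germline = int(tab.table.loc[list(sorted(GERMLINE_LABELS))].to_numpy().sum())
    return {"somatic": somatic, "germline": germline, "total": somatic + germline}


def germline_shift_summary(tab: CrossTab) -> dict[str, int]:
    """Quantify the shift of the germ line toward meiotic profiles.

    spermatogonial_down counts clones from spermatogonial clusters (E, F) that
    fall in the down-regulated response cluster 1; meiotic_up counts clones
    from the meiotic/post-meiotic cluster (H) in the up-regulated response
    clusters 2 and 3.
    """
    t = tab.table
    sg = list(sorted(SPERMATOGONIAL_LABELS))
    return {
        "spermatogonial_down": int(t.loc[sg, 1].sum()),
        "spermatogonial_total": int(t.loc[sg].to_numpy().sum()),
        "meiotic_up": int(t.loc["H", [2, 3]].sum()),
        "meiotic_total": int(t.loc["H"].sum()),
    }


def gene_level_pairs(
    androgen_clusters: pd.Series,
    atlas: DevAtlas,
    clone_to_gene: pd.Series,
) -> pd.DataFrame:
    """Collapse clone labels to genes.

    A gene inherits the labels of its clones; where clones of one gene
    disagree, the gene is counted once per distinct (atlas, cluster) pair and
    a warning is logged (clone- and gene-level totals then differ).
    """
    common = androgen_clusters.index.intersection(atlas.labels.index).intersection(
        clone_to_gene.index
    )
    df = pd.DataFrame(
        {
            "gene": clone_to_gene.loc[common],
            "atlas": atlas.labels.loc[common],
            "cluster": androgen_clusters.loc[common],
        }
    )
    pairs = df.drop_duplicates().reset_index(drop=True)
    conflicted = pairs["gene"].duplicated(keep=False)
    if conflicted.any():
        logger.warning(
            "%d genes have clones with conflicting labels; counted once per distinct pair",
            pairs.loc[conflicted, "gene"].nunique(),
        )
    return pairs
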