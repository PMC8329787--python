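"""Gene-set construction, overlap summaries, sense/antisense
cross-tabulation and hypergeometric over-representation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from asdetect.core import SenseAntisensePair
from asdetect.quant import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    @staticmethod
    def of(name: str, members: Iterable[str]) -> "GeneSet":
        return GeneSet(name=name, members=frozenset(members))


@dataclass
class TermMap:
    """Flat term -> gene mapping over an explicit gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        for term, genes in self.terms.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(f"term {term!r} has genes outside the universe")

    @staticmethod
    def from_tsv(path, universe: Iterable[str]) -> "TermMap":
        """Load a 2-column TSV (term_id, gene_id)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"])
        uni = frozenset(universe)
        terms: dict[str, set[str]] = {}
        for term, gene in zip(df["term"], df["gene"]):
            terms.setdefault(str(term), set()).add(str(gene))
        return TermMap(
            terms={t: frozenset(g & uni) for t, g in terms.items()}, universe=uni
        )


@dataclass
class CrossTab:
    """Counts and per-cell gene lists over sense status x antisense status.

    Rows are the gene's own (sense) differential-expression status; the
    column says whether the gene carries at least one upregulated
    antisense unit. Cells partition the gene universe considered.
    """

    cells: dict[tuple[str, str], list[str]]  # (sense_status, antisense_status)

    SENSE_LEVELS = ("up", "down", "ns")
    AS_LEVELS = ("up", "ns")

    def count(self, sense_status: str, antisense_status: str) -> int:
        return len(self.cells.get((sense_status, antisense_status), []))

    def genes(self, sense_status: str, antisense_status: str) -> list[str]:
        return list(self.cells.get((sense_status, antisense_status), []))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                a: [self.count(s, a) for s in self.SENSE_LEVELS]
                for a in self.AS_LEVELS
            },
            index=list(self.SENSE_LEVELS),
        ).rename_axis(index="sense", columns="antisense")


def build_sets(
    antisense_de: pd.DataFrame,
    sense_de: pd.DataFrame,
    pairs: Sequence[SenseAntisensePair],
) -> dict[str, GeneSet]:
    """Derive the named feature/gene sets from two DE tables and the
    antisense-unit -> gene pairing.

    Emits antisense_up / antisense_down (unit ids), their projections onto
    corresponding sense genes (deduplicated at the gene level),
    sense_up / sense_down (gene ids), and the ATE gene set (any gene
    linked by >= 1 pair). DE tables are indexed by feature with a
    ``status`` column.
    """
    by_feature: dict[str, set[str]] = {}
    for p in pairs:
        by_feature.setdefault(p.feature_id, set()).add(p.gene_id)

    def project(feature_ids: Iterable[str]) -> set[str]:
        genes: set[str] = set()
        for fid in feature_ids:
            genes |= by_feature.get(fid, set())
        return genes

    as_up = set(antisense_de.index[antisense_de["status"] == "up"])
    as_down = set(antisense_de.index[antisense_de["status"] == "down"])
    return {
        "antisense_up": GeneSet.of("antisense_up", as_up),
        "antisense_down": GeneSet.of("antisense_down", as_down),
        "antisense_up_genes": GeneSet.of("antisense_up_genes", project(as_up)),
        "antisense_down_genes": GeneSet.of("antisense_down_genes", project(as_down)),
        "sense_up": GeneSet.of(
            "sense_up", set(sense_de.index[sense_de["status"] == "up"])
        ),
        "sense_down": GeneSet.of(
            "sense_down", set(sense_de.index[sense_de["status"] == "down"])
        ),
        "ate_genes": GeneSet.of("ate_genes", {p.gene_id for p in pairs}),
    }


def set_overlap(a: GeneSet, b: GeneSet) -> tuple[int, int, int, float]:
    """Venn arithmetic: (|a∩b|, |a\\b|, |b\\a|, |a∩b|/|b|).

    Coverage (the fraction of ``b`` found in ``a``) is NaN, with a logged
    warning, when ``b`` is empty.
    """
    inter = len(a.members & b.members)
    only_a = len(a.members - b.members)
    only_b = len(b.members - a.members)
    if len(b.members) == 0:
        logger.warning("coverage undefined: set %r is empty", b.name)
        coverage = float("nan")
    else:
        coverage = inter / len(b.members)
    return inter, only_a, only_b, coverage


def crosstab_sense_antisense(
    sense_de: pd.DataFrame,
    antisense_de: pd.DataFrame,
    pairs: Sequence[SenseAntisensePair],
) -> CrossTab:
    """Cross-tabulate each gene's sense DE status against whether it has
    at least one upregulated antisense unit.

    The universe is the set of genes in ``sense_de``; genes are counted
    once regardless of how many antisense units they pair with.
    """
    as_up_features = set(antisense_de.index[antisense_de["status"] == "up"])
    genes_with_up_as = {
        p.gene_id for p in pairs if p.feature_id in as_up_features
    }
    cells: dict[tuple[str, str], list[str]] = {
        (s, a): [] for s in CrossTab.SENSE_LEVELS for a in CrossTab.AS_LEVELS
    }
    for gene in sense_de.index:
        sense_status = sense_de.loc[gene, "status"]
        as_status = "up" if gene in genes_with_up_as else "ns"
        cells[(sense_status, as_status)].append(gene)
    for cell in cells.values():
        cell.sort()
    return CrossTab(cells=cells)


def crosstab_table(
    crosstab: CrossTab,
    sense_de: pd.DataFrame,
    antisense_de: pd.DataFrame,
    pairs: Sequence[SenseAntisensePair],
    sense_status: str,
) -> pd.DataFrame:
    """Long-form listing of one antisense-up cell: one row per
    (gene, antisense unit) with both features' log2FC and p-value —
    the layout used for reporting co-regulated genes."""
    as_up = set(antisense_de.index[antisense_de["status"] == "up"])
    genes = set(crosstab.genes(sense_status, "up"))
    rows = []
    for p in sorted(pairs, key=lambda p: (p.gene_id, p.feature_id)):
        if p.gene_id in genes and p.feature_id in as_up:
            rows.append(
                (
                    p.gene_id,
                    sense_de.loc[p.gene_id, "log2fc"],
                    sense_de.loc[p.gene_id, "pvalue"],
                    p.feature_id,
                    antisense_de.loc[p.feature_id, "log2fc"],
                    antisense_de.loc[p.feature_id, "pvalue"],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "sense_log2fc",
            "sense_pvalue",
            "antisense_id",
            "antisense_log2fc",
            "antisense_pvalue",
        ],
    )


def hypergeom_enrichment(
    query: GeneSet,
    terms: TermMap,
    enrichment_q: float = 0.05,
    filter_significant: bool = True,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each term.

    Query members outside the universe are dropped with a warning. The
    p-value per term is P(X >= observed overlap) drawing |query| genes
    from the universe; q-values are BH across terms. Returns a DataFrame
    (term, term_size, overlap, pvalue, qvalue) ranked by qvalue, filtered
    at ``qvalue < enrichment_q`` unless ``filter_significant`` is False.
    """
    members = query.members & terms.universe
    dropped = len(query.members) - len(members)
    if dropped:
        logger.warning("%d query genes outside the universe dropped", dropped)
    M = len(terms.universe)
    N = len(members)
    rows = []
    for term, genes in sorted(terms.terms.items()):
        n = len(genes)
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((term, n, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "pvalue"])
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    df = df.sort_values(["qvalue", "pvalue", "term"]).reset_index(drop=True)
    if filter_significant:
        df = df[df["qvalue"] < enrichment_q].reset_index(drop=True)
    return df
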