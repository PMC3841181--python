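"""Agreement between chemo-groups and genetic groups.

The core outputs are (i) a cross-tabulation of the two partitions over
co-scored individuals, (ii) mapping-cardinality fractions — for each
group in one partition, how many groups of the other it touches
(1, 2, >= 3), generalizing the single/two/many breakdown used to
summarize nuclear-versus-mitochondrial concordance, (iii) the adjusted
Rand index as a chance-corrected agreement summary, and (iv) an
exception screen that flags and adjudicates the two departure patterns:
a phylogroup split across chemo-groups, and a chemo-group shared across
phylogroups. PCA geometry decides whether a shared chemistry reflects
convergent acquisition (groups separable in PC space) or a likely
single origin (inseparable), and whether a split is chemically real
(separable) or not differentiated (inseparable).

ARI and the cardinality fractions are this package's chosen
operationalizations of "concordance"; outputs label them as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .chemometrics import ChemoGroups, PCAResult, group_separation
from .genetics import PhylogroupAssignment, phylogroups_are_sister


class ConcordanceError(ValueError):
    pass


@dataclass
class CrossTab:
    counts: pd.DataFrame          # rows = partition A groups, cols = B groups
    only_in_a: list[str] = field(default_factory=list)
    only_in_b: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_margin(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margin(self) -> pd.Series:
        return self.counts.sum(axis=0)


def crosstab(a: dict[str, str], b: dict[str, str]) -> CrossTab:
    """Contingency table of two labelings over their shared individuals.

    Individuals present in only one labelling are excluded but reported,
    never silently dropped.
    """
    shared = [i for i in a if i in b]
    if not shared:
        raise ConcordanceError("no individuals shared between the two labelings")
    df = pd.crosstab(
        pd.Series([a[i] for i in shared], name="a"),
        pd.Series([b[i] for i in shared], name="b"),
    )
    return CrossTab(
        counts=df,
        only_in_a=sorted(i for i in a if i not in b),
        only_in_b=sorted(i for i in b if i not in a),
    )


def mapping_cardinality(ct: CrossTab) -> dict:
    """Per-row-group mapping cardinality, binned as {1, 2, >= 3}.

    For each row group, cardinality = number of column groups with a
    nonzero count. Fractions are over nonempty row groups and sum to 1;
    the exact per-cardinality detail is also returned.
    """
    counts = ct.counts.to_numpy()
    nonempty = counts.sum(axis=1) > 0
    cards = (counts[nonempty] > 0).sum(axis=1)
    n = int(nonempty.sum())
    if n == 0:
        raise ConcordanceError("cross-tab has no nonempty row groups")
    detail: dict[int, int] = {}
    for c in cards:
        detail[int(c)] = detail.get(int(c), 0) + 1
    return {
        "fraction_one": float(np.sum(cards == 1) / n),
        "fraction_two": float(np.sum(cards == 2) / n),
        "fraction_three_plus": float(np.sum(cards >= 3) / n),
        "detail": {str(k): v for k, v in sorted(detail.items())},
        "n_groups": n,
    }


def adjusted_rand(a: dict[str, str], b: dict[str, str]) -> float:
    """Adjusted Rand index over shared individuals.

    1 for identical partitions (up to relabelling); expectation 0 under
    random labelling. The doubly-degenerate case (both partitions a
    single group) is identical-by-definition and returns 1.
    """
    shared = [i for i in a if i in b]
    if len(shared) < 2:
        raise ConcordanceError("need at least 2 shared individuals")
    la = [a[i] for i in shared]
    lb = [b[i] for i in shared]
    return float(adjusted_rand_score(la, lb))


@dataclass
class ExceptionRecord:
    pattern: str            # "split_phylogroup" | "shared_chemistry"
    focal_group: str        # the group exhibiting the pattern
    members: tuple[str, str]  # the pair of groups on the other side
    separation_ratio: float
    separation_call: str
    verdict: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["members"] = list(self.members)
        return d


def exception_screen(chemo: ChemoGroups | dict[str, str],
                     phylo: PhylogroupAssignment | dict[str, str],
                     pca_result: PCAResult,
                     tree: dendropy.Tree | None = None,
                     dims: int = 2, s_sep: float = 2.0,
                     s_overlap: float = 1.0) -> list[ExceptionRecord]:
    """Flag and adjudicate departures from one-to-one concordance.

    Pattern (i), split phylogroup: one phylogroup spanning >= 2
    chemo-groups. Its chemo-subsets are compared in PC space; an
    overlapping pair means the chemical split is not corroborated
    ("not-differentiated"), a separated pair means genuinely distinct
    chemotypes within the phylogroup ("distinct-chemotypes").

    Pattern (ii), shared chemistry: one chemo-group spanning >= 2
    phylogroups. Separated phylogroup subsets indicate independent,
    convergent acquisition of the same compound suite ("convergent");
    overlapping subsets indicate a single origin — reported as
    "single-origin-candidate" when the phylogroups are adjacent on a
    supplied tree or no tree is given, "unresolved" when the tree shows
    them distant.
    """
    chemo_map = chemo.assignment if isinstance(chemo, ChemoGroups) else dict(chemo)
    phylo_map = (phylo.assignment if isinstance(phylo, PhylogroupAssignment)
                 else dict(phylo))
    shared = [i for i in chemo_map if i in phylo_map]
    if len(shared) < 2:
        raise ConcordanceError("need at least 2 co-scored individuals")
    in_pca = set(pca_result.ids)
    missing = [i for i in shared if i not in in_pca]
    if missing:
        raise ConcordanceError(f"PCA result missing individuals: {missing}")

    by_pg: dict[str, list[str]] = {}
    by_cg: dict[str, list[str]] = {}
    for ind in shared:
        by_pg.setdefault(phylo_map[ind], []).append(ind)
        by_cg.setdefault(chemo_map[ind], []).append(ind)

    records: list[ExceptionRecord] = []

    # (i) split phylogroup: one phylogroup, >= 2 chemo-groups
    for pg, members in sorted(by_pg.items()):
        cgs = sorted({chemo_map[i] for i in members})
        if len(cgs) < 2:
            continue
        labels = {i: chemo_map[i] for i in members}
        for rep in group_separation(pca_result, labels, dims=dims,
                                    s_sep=s_sep, s_overlap=s_overlap):
            if rep.call == "overlapping":
                verdict = "not-differentiated"
            elif rep.call == "separated":
                verdict = "distinct-chemotypes"
            else:
                verdict = "indeterminate"
            records.append(ExceptionRecord(
                pattern="split_phylogroup", focal_group=pg,
                members=(rep.group_a, rep.group_b),
                separation_ratio=rep.ratio, separation_call=rep.call,
                verdict=verdict,
            ))

    # (ii) shared chemistry: one chemo-group, >= 2 phylogroups
    for cg, members in sorted(by_cg.items()):
        pgs = sorted({phylo_map[i] for i in members})
        if len(pgs) < 2:
            continue
        labels = {i: phylo_map[i] for i in members}
        reports = group_separation(pca_result, labels, dims=dims,
                                   s_sep=s_sep, s_overlap=s_overlap)
        for rep in reports:
            if rep.call == "separated":
                verdict = "convergent"
            elif rep.call == "overlapping":
                tips_a = [i for i in members if phylo_map[i] == rep.group_a]
                tips_b = [i for i in members if phylo_map[i] == rep.group_b]
                if tree is None or phylogroups_are_sister(tree, tips_a, tips_b):
                    verdict = "single-origin-candidate"
                else:
                    verdict = "unresolved"
            else:
                verdict = "indeterminate"
            records.append(ExceptionRecord(
                pattern="shared_chemistry", focal_group=cg,
                members=(rep.group_a, rep.group_b),
                separation_ratio=rep.ratio, separation_call=rep.call,
                verdict=verdict,
            ))
    return records


@dataclass
class ConcordanceReport:
    crosstab: CrossTab
    cardinality: dict
    agreement_index: float
    exceptions: list[ExceptionRecord]

    def to_dict(self) -> dict:
        ratio_safe = lambda r: r if np.isfinite(r) else None  # noqa: E731
        return {
            "crosstab": {
                "rows": list(self.crosstab.counts.index),
                "columns": list(self.crosstab.counts.columns),
                "counts": self.crosstab.counts.to_numpy().tolist(),
                "total": self.crosstab.total,
                "only_in_a": self.crosstab.only_in_a,
                "only_in_b": self.crosstab.only_in_b,
            },
            "mapping_cardinality": self.cardinality,
            "agreement_index": {
                "statistic": "adjusted_rand_index",
                "note": ("package operationalization of chemo-genetic "
                         "concordance; not a published statistic"),
                "value": self.agreement_index,
            },
            "exceptions": [
                {**e.to_dict(),
                 "separation_ratio": ratio_safe(e.separation_ratio)}
                for e in self.exceptions
            ],
        }


def concordance_report(chemo: ChemoGroups | dict[str, str],
                       phylo: PhylogroupAssignment | dict[str, str],
                       pca_result: PCAResult,
                       tree: dendropy.Tree | None = None,
                       dims: int = 2, s_sep: float = 2.0,
                       s_overlap: float = 1.0) -> ConcordanceReport:
    """Full agreement report: cross-tab, cardinality, ARI, exceptions."""
    chemo_map = chemo.assignment if isinstance(chemo, ChemoGroups) else dict(chemo)
    phylo_map = (phylo.assignment if isinstance(phylo, PhylogroupAssignment)
                 else dict(phylo))
    ct = crosstab(chemo_map, phylo_map)
    return ConcordanceReport(
        crosstab=ct,
        cardinality=mapping_cardinality(ct),
        agreement_index=adjusted_rand(chemo_map, phylo_map),
        exceptions=exception_screen(chemo, phylo, pca_result, tree=tree,
                                    dims=dims, s_sep=s_sep, s_overlap=s_overlap),
    )


def write_report_json(report: ConcordanceReport, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
    return path


def write_crosstab_tsv(ct: CrossTab, path: str | Path) -> Path:
    path = Path(path)
    ct.counts.to_csv(path, sep="\t")
    return path
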