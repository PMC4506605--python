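"""Hub/bottleneck classification and drug-association lookup.

In scale-free interaction networks the highly connected nodes (hubs) and
the high-betweenness nodes (bottlenecks) are the proteins whose removal
most disrupts the network, which makes them the prime candidates for drug
targeting.  The classification rule here is relative: a node is a hub iff
its degree is at least half the maximum degree in the table, and a
bottleneck iff its betweenness is at least half the maximum betweenness
(both inclusive, so boundary values produced by rounding are retained).
A protein is called a *putative target* iff it is a hub; bottleneck status
is reported alongside as an auxiliary flag.

Known drugs are joined in from a gene-symbol-to-drug association table.
The bundled default table reproduces the published drug associations for
the sperm-egg adhesion hubs (FN1, EGFR, ITGAV, ITGB3, COL1A1, ITGB5);
hubs without a known drug (e.g. CD9) simply get an empty drug list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .model import ValidationError

__all__ = [
    "TargetCall",
    "classify_targets",
    "map_drugs",
    "target_report",
    "read_drug_associations",
    "bundled_drug_associations",
    "bundled_reported_centralities",
]

#: Gene symbol -> tuple of drug names.
DrugAssociationTable = Mapping[str, tuple[str, ...]]


@dataclass(frozen=True)
class TargetCall:
    """One protein's hub/bottleneck classification plus mapped drugs."""

    accession: str
    gene_symbol: str
    degree: int
    betweenness: float
    closeness: float
    is_hub: bool
    is_bottleneck: bool
    drugs: tuple[str, ...] = ()


def classify_targets(tbl: pd.DataFrame) -> list[TargetCall]:
    """Apply the half-of-maximum hub and bottleneck criteria.

    Parameters
    ----------
    tbl
        Centrality table with columns ``accession``, ``gene_symbol``,
        ``degree``, ``betweenness``, ``closeness`` (one row per node).

    Returns
    -------
    list of TargetCall
        One call per row, sorted by degree descending, betweenness
        descending, then gene symbol ascending.  ``is_hub`` is True iff
        degree >= max(degree)/2; ``is_bottleneck`` iff betweenness >=
        max(betweenness)/2 (both inclusive).

    Raises
    ------
    ValidationError
        On an empty table.
    """
    if len(tbl) == 0:
        raise ValidationError("cannot classify targets on an empty centrality table")
    max_deg = float(tbl["degree"].max())
    max_bc = float(tbl["betweenness"].max())
    calls = [
        TargetCall(
            accession=str(row.accession),
            gene_symbol=str(row.gene_symbol),
            degree=int(row.degree),
            betweenness=float(row.betweenness),
            closeness=float(row.closeness),
            is_hub=float(row.degree) >= max_deg / 2.0,
            is_bottleneck=float(row.betweenness) >= max_bc / 2.0,
        )
        for row in tbl.itertuples(index=False)
    ]
    calls.sort(key=lambda c: (-c.degree, -c.betweenness, c.gene_symbol))
    return calls


def map_drugs(
    calls: Sequence[TargetCall], assoc: DrugAssociationTable
) -> list[TargetCall]:
    """Populate each call's drug list from the association table.

    Lookup is by gene symbol; symbols absent from the table get an empty
    list.  Ordering and all other fields are preserved.
    """
    return [replace(c, drugs=tuple(assoc.get(c.gene_symbol, ()))) for c in calls]


def target_report(calls: Sequence[TargetCall], path: str | Path) -> None:
    """Write target calls as a TSV, drugs semicolon-separated."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "accession",
                "gene_symbol",
                "degree",
                "betweenness",
                "closeness",
                "is_hub",
                "is_bottleneck",
                "drugs",
            ]
        )
        for c in calls:
            writer.writerow(
                [
                    c.accession,
                    c.gene_symbol,
                    c.degree,
                    f"{c.betweenness:.6g}",
                    f"{c.closeness:.6g}",
                    int(c.is_hub),
                    int(c.is_bottleneck),
                    ";".join(c.drugs),
                ]
            )


def read_drug_associations(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column (gene_symbol, drug) TSV into an association table.

    Multiple rows per symbol accumulate; drug order follows file order.
    """
    out: dict[str, list[str]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not reader.fieldnames or "gene_symbol" not in reader.fieldnames or "drug" not in reader.fieldnames:
            from .model import FormatError

            raise FormatError(f"{path}: expected columns gene_symbol, drug")
        for row in reader:
            sym = (row["gene_symbol"] or "").strip()
            drug = (row["drug"] or "").strip()
            if sym and drug:
                out.setdefault(sym, []).append(drug)
    return {k: tuple(v) for k, v in out.items()}


def _data_path(name: str):
    return resources.files("gametenet").joinpath("data", name)


def bundled_drug_associations() -> dict[str, tuple[str, ...]]:
    """The default gene-symbol-to-drug association table shipped with the package."""
    with resources.as_file(_data_path("drug_associations.tsv")) as p:
        return read_drug_associations(p)


def bundled_reported_centralities() -> pd.DataFrame:
    """Reference centrality values for the 13 highly connected proteins of a
    curated human sperm-egg interaction network (106 nodes), bundled as a
    regression fixture and demo input.

    Columns: ``gene_symbol``, ``protein_family``, ``degree``,
    ``betweenness``, ``closeness``.  Gene symbols double as accessions when
    this table is fed to :func:`classify_targets`.
    """
    with resources.as_file(_data_path("reported_hub_centralities.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["accession"] = df["gene_symbol"]
    return df[
        ["accession", "gene_symbol", "protein_family", "degree", "betweenness", "closeness"]
    ]
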