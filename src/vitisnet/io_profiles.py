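"""Reading, validation and export of metabolite profile tables and networks.

The central container is :class:`ProfileMatrix`: a samples x metabolites table
of non-negative relative intensities (GC/MS or LC/MS peak areas after platform
normalization) together with the sample metadata of a two-cultivar x
two-treatment x multi-day design. Missing measurements are kept as explicit
NaN, never silently zeroed, and are excluded pairwise downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "MISSING_TOKENS",
    "read_profile_table",
    "write_profile_table",
    "read_metadata_table",
    "read_annotation_table",
    "read_trait_table",
    "merge_platforms",
    "split_conditions",
    "export_network",
    "export_comparison",
    "read_network_edgelist",
    "read_network_graphml",
]

#: Cell contents accepted as "measurement missing" on input.
MISSING_TOKENS = ("", "NA", "NaN", "nan")

METADATA_COLUMNS = ("cultivar", "treatment", "day", "replicate")

PLATFORMS = ("GC", "LC", "sap")


def _sniff_delimiter(path: Path) -> str:
    """Pick tab or comma from the header line; tabs win when both occur."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError(f"{path}: header contains neither tab nor comma delimiter")


@dataclass
class ProfileMatrix:
    """Samples x metabolites intensity table with attached sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id, one float column per metabolite.
        NaN marks an explicitly missing measurement.
    samples
        DataFrame indexed by sample_id with columns cultivar, treatment, day,
        replicate; row order matches ``values``.
    platforms
        Series mapping metabolite id -> platform tag ("GC", "LC" or "sap").
    scale
        "intensity" (non-negative, the on-disk representation) or "log10"
        (after :func:`vitisnet.preprocess.log_transform`).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    platforms: pd.Series = field(default=None)  # type: ignore[assignment]
    scale: str = "intensity"

    def __post_init__(self) -> None:
        if self.platforms is None:
            self.platforms = pd.Series("GC", index=self.values.columns)
        self.values = self.values.astype(float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = sorted(set(self.values.columns[self.values.columns.duplicated()]))
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        missing_meta = idx.difference(self.samples.index)
        if len(missing_meta):
            raise ValueError(
                "samples without metadata: " + ", ".join(map(str, missing_meta))
            )
        self.samples = self.samples.loc[idx]
        for col in METADATA_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        design = self.samples[list(METADATA_COLUMNS)]
        if design.duplicated().any():
            raise ValueError("duplicate (cultivar, treatment, day, replicate) rows")
        if self.scale == "intensity":
            vals = self.values.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                bad = self.values.columns[(self.values < 0).any(axis=0)]
                raise ValueError(
                    f"negative intensities in columns: {list(bad)}"
                )
        extra = self.platforms.index.symmetric_difference(self.values.columns)
        if len(extra):
            raise ValueError(f"platform tags and metabolite ids disagree: {list(extra)}")

    # -- conveniences -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(
            self.values.copy(), self.samples.copy(), self.platforms.copy(), self.scale
        )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ProfileMatrix":
        """Return a sibling matrix with replaced values (metadata shared)."""
        platforms = self.platforms.loc[values.columns]
        return ProfileMatrix(
            values, self.samples.loc[values.index], platforms, scale or self.scale
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ProfileMatrix":
        return ProfileMatrix(
            self.values.loc[list(sample_ids)],
            self.samples.loc[list(sample_ids)],
            self.platforms.copy(),
            self.scale,
        )

    def subset(self, cultivar=None, treatment=None, day=None) -> "ProfileMatrix":
        mask = pd.Series(True, index=self.samples.index)
        if cultivar is not None:
            mask &= self.samples["cultivar"] == cultivar
        if treatment is not None:
            mask &= self.samples["treatment"] == treatment
        if day is not None:
            days = [day] if np.isscalar(day) else list(day)
            mask &= self.samples["day"].isin(days)
        return self.select_samples(list(self.samples.index[mask]))


def read_metadata_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a sample metadata table (sample_id, cultivar, treatment, day, replicate)."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    meta = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: first column must be sample_id")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(set(meta.loc[meta["sample_id"].duplicated(), "sample_id"]))
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    meta = meta.set_index("sample_id")
    meta["day"] = meta["day"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


def read_profile_table(
    path: str | Path,
    platform: str = "GC",
    metadata_path: str | Path | None = None,
    metadata: pd.DataFrame | None = None,
    delimiter: str | None = None,
) -> ProfileMatrix:
    """Read a wide profile table (first column sample_id, one column per metabolite).

    Unparseable cells become explicit missing values; accepted missing tokens
    are "", "NA" and "NaN". Duplicate sample ids, samples without metadata and
    negative intensities are hard errors.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"{path}: duplicate sample ids: {dupes}")
    body = raw.drop(columns=[id_col])
    # metabolite ids: trimmed, case preserved
    body.columns = [c.strip() for c in body.columns]
    values = body.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    values.index = pd.Index(ids, name="sample_id")
    if metadata is None:
        if metadata_path is None:
            raise ValueError("either metadata_path or metadata must be given")
        metadata = read_metadata_table(metadata_path, delimiter=delimiter)
    platforms = pd.Series(platform, index=values.columns)
    return ProfileMatrix(values, metadata, platforms)


def write_profile_table(
    pm: ProfileMatrix,
    path: str | Path,
    metadata_path: str | Path | None = None,
    delimiter: str = "\t",
) -> None:
    """Write a ProfileMatrix back to disk (missing values as 'NA')."""
    out = pm.values.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep=delimiter, index=False, na_rep="NA")
    if metadata_path is not None:
        meta = pm.samples.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(metadata_path, sep=delimiter, index=False)


def read_annotation_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read metabolite annotations: metabolite_id, compound_class[, tier]."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    ann = pd.read_csv(path, sep=sep, dtype=str)
    if "metabolite_id" not in ann.columns or "compound_class" not in ann.columns:
        raise ValueError(f"{path}: need metabolite_id and compound_class columns")
    ann["metabolite_id"] = ann["metabolite_id"].str.strip()
    if ann["metabolite_id"].duplicated().any():
        dupes = sorted(set(ann.loc[ann["metabolite_id"].duplicated(), "metabolite_id"]))
        raise ValueError(f"duplicate annotations for: {dupes}")
    return ann.set_index("metabolite_id")


def read_trait_table(
    path: str | Path,
    profile: ProfileMatrix | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a per-sample physiological trait table (Psi_l, g_s, pi, A_N, ABA, C/N...)."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    traits = pd.read_csv(path, sep=sep, dtype={"sample_id": str}).set_index("sample_id")
    traits = traits.apply(pd.to_numeric, errors="coerce")
    if profile is not None:
        unknown = traits.index.difference(profile.values.index)
        if len(unknown):
            raise ValueError(
                "trait samples absent from profile: " + ", ".join(map(str, unknown))
            )
    return traits


def merge_platforms(
    gc: ProfileMatrix, lc: ProfileMatrix, policy: str = "keep_gc"
) -> tuple[ProfileMatrix, list[str]]:
    """Merge GC/MS and LC/MS matrices over the same samples.

    Metabolites detected on both platforms are collapsed to one representative
    column. Policies: ``keep_gc`` (default), ``keep_lc``, ``keep_both`` (the
    overlapping ids are retained with ``_GC``/``_LC`` suffixes, for the case
    where the two platforms disagree and both readings should be inspected).

    Returns the merged matrix and the list of collapsed metabolite ids.
    """
    if set(gc.sample_ids) != set(lc.sample_ids):
        raise ValueError("GC and LC matrices cover different sample sets")
    lc = lc.select_samples(gc.sample_ids)
    overlap = [m for m in gc.metabolites if m in set(lc.metabolites)]
    if policy == "keep_gc":
        lc_keep = lc.values.drop(columns=overlap)
        values = pd.concat([gc.values, lc_keep], axis=1)
        platforms = pd.concat([gc.platforms, lc.platforms.drop(overlap)])
    elif policy == "keep_lc":
        gc_keep = gc.values.drop(columns=overlap)
        values = pd.concat([gc_keep, lc.values], axis=1)
        platforms = pd.concat([gc.platforms.drop(overlap), lc.platforms])
    elif policy == "keep_both":
        gc_vals = gc.values.rename(columns={m: f"{m}_GC" for m in overlap})
        lc_vals = lc.values.rename(columns={m: f"{m}_LC" for m in overlap})
        values = pd.concat([gc_vals, lc_vals], axis=1)
        platforms = pd.concat(
            [
                gc.platforms.rename({m: f"{m}_GC" for m in overlap}),
                lc.platforms.rename({m: f"{m}_LC" for m in overlap}),
            ]
        )
    else:
        raise ValueError(f"unknown merge policy {policy!r}")
    merged = ProfileMatrix(values, gc.samples.copy(), platforms, gc.scale)
    return merged, overlap


def split_conditions(
    pm: ProfileMatrix,
    day4: str = "both",
    prediv_day: int | None = None,
) -> dict[tuple[str, str], ProfileMatrix]:
    """Split a profile matrix into one matrix per cultivar x treatment.

    Samples from the pre-divergence day (the first design day, when the two
    irrigation regimes were still identical) are assigned to *both* arms by
    default (``day4="both"``); ``day4="own"`` keeps them in their labeled arm
    and ``day4="drop"`` excludes them.
    """
    days = sorted(pm.samples["day"].unique())
    if prediv_day is None:
        prediv_day = days[0]
    out: dict[tuple[str, str], ProfileMatrix] = {}
    for cultivar in sorted(pm.samples["cultivar"].unique()):
        for treatment in sorted(pm.samples["treatment"].unique()):
            meta = pm.samples
            own = (meta["cultivar"] == cultivar) & (meta["treatment"] == treatment)
            if day4 == "both":
                mask = own & (meta["day"] != prediv_day)
                mask |= (meta["cultivar"] == cultivar) & (meta["day"] == prediv_day)
            elif day4 == "drop":
                mask = own & (meta["day"] != prediv_day)
            elif day4 == "own":
                mask = own
            else:
                raise ValueError(f"unknown day4 policy {day4!r}")
            out[(cultivar, treatment)] = pm.select_samples(list(meta.index[mask]))
    return out


# -- network export -------------------------------------------------------

def _ordered_edges(graph: nx.Graph) -> list[tuple[str, str, dict]]:
    edges = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        edges.append((a, b, data))
    return sorted(edges, key=lambda e: (e[0], e[1]))


def export_network(
    net,
    path: str | Path,
    fmt: str = "edgelist",
    annotations: Mapping[str, str] | pd.DataFrame | None = None,
) -> None:
    """Write a correlation network as an edge-list TSV or GraphML file.

    The edge list has columns node_a, node_b, r, origin with node_a < node_b
    and rows sorted lexicographically, so exports are byte-deterministic. An
    empty network produces a header-only file. GraphML nodes carry degree and
    (when annotations are given) compound_class attributes.
    """
    graph = net.graph if hasattr(net, "graph") else net
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["node_a", "node_b", "r", "origin"])
            for a, b, data in _ordered_edges(graph):
                writer.writerow(
                    [a, b, f"{data.get('r', float('nan')):.6f}", data.get("origin", "")]
                )
    elif fmt == "graphml":
        g = nx.Graph()
        classes = None
        if annotations is not None:
            if isinstance(annotations, pd.DataFrame):
                classes = annotations["compound_class"].to_dict()
            else:
                classes = dict(annotations)
        for node in sorted(graph.nodes, key=str):
            attrs = {"degree": int(graph.degree(node))}
            if classes is not None:
                attrs["compound_class"] = str(classes.get(node, "other"))
            g.add_node(node, **attrs)
        for a, b, data in _ordered_edges(graph):
            g.add_edge(a, b, r=float(data.get("r", float("nan"))))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def export_comparison(comparison, path: str | Path) -> None:
    """Write a network comparison as an edge list with an origin label column."""
    path = Path(path)
    rows = []
    for label, edges in (
        ("shared", comparison.shared),
        (f"{comparison.label_a}-specific", comparison.a_specific),
        (f"{comparison.label_b}-specific", comparison.b_specific),
    ):
        for edge in edges:
            a, b = sorted(map(str, edge))
            r_a, r_b = comparison.edge_r.get(tuple(sorted(edge)), (None, None))
            r = r_a if r_a is not None else r_b
            rows.append((a, b, r, label))
    rows.sort(key=lambda t: (t[3], t[0], t[1]))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_a", "node_b", "r", "origin"])
        for a, b, r, label in rows:
            writer.writerow([a, b, "" if r is None else f"{r:.6f}", label])


def read_network_edgelist(path: str | Path) -> nx.Graph:
    """Read an edge-list TSV written by :func:`export_network`."""
    graph = nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        attrs = {}
        if not pd.isna(row.get("r", np.nan)):
            attrs["r"] = float(row["r"])
        origin = row.get("origin", "")
        if isinstance(origin, str) and origin:
            attrs["origin"] = origin
        graph.add_edge(str(row["node_a"]), str(row["node_b"]), **attrs)
    return graph


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
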