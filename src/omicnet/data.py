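"""Data model, file I/O and configuration shared by every pipeline stage.

The universal input is an :class:`OmicsStudy`: one feature-by-sample value
matrix assembled from several omic classes (gene transcripts, lipids,
metabolites, plasma biochemicals, anthropometric parameters), plus feature
metadata and a sample-to-group map.  Thresholds that drive the filter
cascades live in :class:`AnalysisConfig` so that every stage reads the same
numbers and every output can embed the configuration hash and RNG seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("omicnet")
if not logger.handlers:  # stderr by default, configurable by the caller
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s omicnet.%(module)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

OMIC_CLASSES = ("gene", "lipid", "metabolite", "biochemical", "anthropometric")

#: values accepted as missing on read; missing stays missing, never zero
NA_VALUES = ["", "NA", "NaN", "nan"]


class OmicsStudyError(ValueError):
    """Raised when an input study violates the data-model invariants."""


@dataclass
class OmicsStudy:
    """Feature x sample numeric matrix with feature and sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature_id with one column per sample.  Gene,
        lipid and metabolite values are expected on a log2-like scale;
        anthropometric values may be on their native scale (only the sign of
        mean differences is used for them downstream).
    feature_meta
        DataFrame indexed by feature_id with at least an ``omic_class``
        column (one of :data:`OMIC_CLASSES`); lipids may carry
        ``lipid_class`` (e.g. ``"TG"``) and ``acyl_chains``
        (slash-separated, e.g. ``"16:0/20:5/22:6"``).
    sample_meta
        DataFrame indexed by sample_id with a ``group`` column.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fid = self.values.index
        if fid.duplicated().any():
            dups = fid[fid.duplicated()].unique().tolist()
            raise OmicsStudyError(f"duplicate feature_id(s): {dups}")
        if self.sample_meta.index.duplicated().any():
            dups = self.sample_meta.index[self.sample_meta.index.duplicated()].unique().tolist()
            raise OmicsStudyError(f"duplicate sample_id(s): {dups}")
        missing_meta = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing_meta:
            raise OmicsStudyError(f"samples absent from sample_meta: {missing_meta}")
        extra_meta = [s for s in self.sample_meta.index if s not in self.values.columns]
        if extra_meta:
            raise OmicsStudyError(f"sample_meta rows without matrix columns: {extra_meta}")
        missing_feat = [f for f in fid if f not in self.feature_meta.index]
        if missing_feat:
            raise OmicsStudyError(f"features absent from feature_meta: {missing_feat[:10]}")
        if "group" not in self.sample_meta.columns:
            raise OmicsStudyError("sample_meta must have a 'group' column")
        if self.sample_meta["group"].isna().any():
            raise OmicsStudyError("every sample must have exactly one group label")
        if self.sample_meta["group"].nunique() < 2:
            raise OmicsStudyError("need >= 2 groups")
        if "omic_class" not in self.feature_meta.columns:
            raise OmicsStudyError("feature_meta must have an 'omic_class' column")
        bad = set(self.feature_meta["omic_class"]) - set(OMIC_CLASSES)
        if bad:
            raise OmicsStudyError(f"unknown omic_class values: {sorted(bad)}")
        # align metadata order with the matrix
        self.feature_meta = self.feature_meta.loc[fid]
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return sorted(self.sample_meta["group"].unique())

    def samples_in_group(self, group: str) -> list[str]:
        if group not in set(self.sample_meta["group"]):
            raise KeyError(f"unknown group {group!r}; have {self.groups}")
        return list(self.sample_meta.index[self.sample_meta["group"] == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in_group(group)]

    def features_of_class(self, omic_class: str) -> list[str]:
        return list(self.feature_meta.index[self.feature_meta["omic_class"] == omic_class])


@dataclass
class AnalysisConfig:
    """Thresholds and knobs for the whole pipeline (defaults as used throughout).

    The node gate keeps features whose disease-contrast BH q is below
    ``node_fdr`` (with the raw p also below ``reversal_p`` for the
    categorization gate); edge retention requires per-group correlation p
    below ``edge_group_p`` in every group, Fisher combined p below
    ``edge_fisher_p`` and BH q within the block-pair family below
    ``edge_fdr``.  Single-cell assignment and the meta-analysis signature use
    the ``sc_*`` and ``meta_*`` thresholds respectively.
    """

    node_fdr: float = 0.10
    reversal_p: float = 0.05
    edge_group_p: float = 0.20
    edge_fisher_p: float = 0.05
    edge_fdr: float = 0.10
    sc_umi_min: float = 1.0
    sc_log2fc_min: float = 0.25
    sc_p_max: float = 0.05
    meta_fdr: float = 0.15
    meta_fisher_p: float = 0.05
    top_fraction: float = 0.10
    regulator_degree_min: int = 50
    regulator_bibc_top_fraction: float = 0.01
    n_random_networks: int = 5000
    rng_seed: int = 0
    null_node_strategy: str = "degree_matched"

    def __post_init__(self) -> None:
        for name in ("reversal_p", "edge_group_p", "edge_fisher_p", "sc_p_max",
                     "meta_fisher_p", "node_fdr", "edge_fdr", "meta_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} must be in (0, 1]")
        for name in ("top_fraction", "regulator_bibc_top_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} must be in (0, 1)")
        if self.n_random_networks < 1:
            raise ValueError("n_random_networks must be >= 1")
        if self.null_node_strategy not in ("degree_matched", "random_node", "all_nodes"):
            raise ValueError(f"unknown null_node_strategy {self.null_node_strategy!r}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a TSV (or, by sniffing, CSV) table; first column is the identifier."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, index_col=index_col,
                       na_values=NA_VALUES, keep_default_na=False, comment="#")


def load_study(value_paths: Sequence[str | Path],
               feature_meta_path: str | Path,
               sample_meta_path: str | Path) -> OmicsStudy:
    """Assemble an :class:`OmicsStudy` from one or more matrix files.

    Features from multiple files are concatenated; a feature appearing in
    more than one file is a hard error naming the feature, as is any sample
    present in a matrix but absent from the sample metadata.
    """
    frames = []
    seen: dict[str, Path] = {}
    for p in value_paths:
        df = _read_table(p)
        for f in df.index:
            if f in seen:
                raise OmicsStudyError(f"feature {f!r} present in both {seen[f]} and {p}")
            seen[f] = Path(p)
        frames.append(df)
    values = pd.concat(frames, axis=0)
    values = values.apply(pd.to_numeric)
    feature_meta = _read_table(feature_meta_path)
    sample_meta = _read_table(sample_meta_path)
    sample_meta.index = sample_meta.index.astype(str)
    values.columns = values.columns.astype(str)
    study = OmicsStudy(values=values, feature_meta=feature_meta, sample_meta=sample_meta)
    logger.info("loaded study: %d features, %d samples, %d groups",
                values.shape[0], values.shape[1], len(study.groups))
    return study


def write_study(study: OmicsStudy, directory: str | Path) -> dict[str, Path]:
    """Write a study as TSV files (one matrix per omic class + metadata).

    Produces ``<class>.tsv`` value matrices, ``features.tsv`` and
    ``samples.tsv``; :func:`load_study` on the returned paths reproduces
    the study.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for omic in study.feature_meta["omic_class"].unique():
        sub = study.values.loc[study.features_of_class(omic)]
        p = directory / f"{omic}.tsv"
        sub.to_csv(p, sep="\t", index_label="feature_id", na_rep="NA",
                   float_format="%.12g")
        paths[omic] = p
    fp = directory / "features.tsv"
    study.feature_meta.to_csv(fp, sep="\t", index_label="feature_id", na_rep="NA")
    sp = directory / "samples.tsv"
    study.sample_meta.to_csv(sp, sep="\t", index_label="sample_id")
    paths["features"] = fp
    paths["samples"] = sp
    return paths


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> member ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_ligand_receptor_table(path: str | Path) -> pd.DataFrame:
    """Read a 2+ column ligand-receptor pair table (ligand, receptor[, source])."""
    df = _read_table(path, index_col=None)
    df = df.rename(columns={df.columns[0]: "ligand", df.columns[1]: "receptor"})
    return df


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("edge_tsv", "graphml", "sif")


def export_network(network: nx.Graph, path: str | Path, format: str = "edge_tsv",
                   config: AnalysisConfig | None = None) -> None:
    """Write a reconstructed network to disk.

    ``edge_tsv`` writes one row per edge with every edge attribute plus a
    ``<path>.nodes.tsv`` sidecar with the node attributes; ``graphml`` and
    ``sif`` use the standard formats.  Re-importing an exported network
    (``read_network``) reproduces nodes, edges and attributes.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {NETWORK_FORMATS}")
    path = Path(path)
    if network.number_of_nodes() == 0:
        logger.warning("exporting empty network to %s", path)
    if config is not None:
        network.graph["config_hash"] = config.hash()
        network.graph["rng_seed"] = int(config.rng_seed)
    if format == "graphml":
        g = network.copy()
        for _, _, d in g.edges(data=True):
            for k, v in list(d.items()):
                if isinstance(v, (np.floating, np.integer)):
                    d[k] = v.item()
        for _, d in g.nodes(data=True):
            for k, v in list(d.items()):
                if isinstance(v, (np.floating, np.integer)):
                    d[k] = v.item()
                elif v is None or (isinstance(v, float) and np.isnan(v)):
                    del d[k]
        nx.write_graphml(g, path)
        return
    if format == "sif":
        with open(path, "w") as fh:
            for u, v, d in network.edges(data=True):
                sign = d.get("sign", 0)
                rel = "pos" if sign > 0 else ("neg" if sign < 0 else "cor")
                fh.write(f"{u}\t{rel}\t{v}\n")
            for n in nx.isolates(network):
                fh.write(f"{n}\n")
        return
    # edge_tsv + node sidecar
    edge_rows = []
    for u, v, d in network.edges(data=True):
        row = {"node_u": u, "node_v": v}
        row.update(d)
        edge_rows.append(row)
    edf = pd.DataFrame(edge_rows, columns=None if edge_rows else ["node_u", "node_v"])
    node_rows = []
    for n, d in network.nodes(data=True):
        row = {"node_id": n}
        row.update(d)
        node_rows.append(row)
    ndf = pd.DataFrame(node_rows, columns=None if node_rows else ["node_id"])
    header = ""
    if config is not None:
        header = f"# config_hash={config.hash()} rng_seed={config.rng_seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        edf.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    with open(path.with_suffix(path.suffix + ".nodes.tsv"), "w") as fh:
        fh.write(header)
        ndf.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_network(path: str | Path, format: str = "edge_tsv") -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown format {format!r}; supported: {NETWORK_FORMATS}")
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) >= 3:
                    sign = {"pos": 1, "neg": -1}.get(parts[1], 0)
                    g.add_edge(parts[0], parts[2], sign=sign)
        return g
    edf = pd.read_csv(path, sep="\t", comment="#")
    ndf = pd.read_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", comment="#")
    g = nx.Graph()
    for _, row in ndf.iterrows():
        attrs = {k: v for k, v in row.items() if k != "node_id" and pd.notna(v)}
        g.add_node(row["node_id"], **attrs)
    for _, row in edf.iterrows():
        attrs = {k: v for k, v in row.items() if k not in ("node_u", "node_v") and pd.notna(v)}
        g.add_edge(row["node_u"], row["node_v"], **attrs)
    return g
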