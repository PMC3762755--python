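"""Signatures and probe -> gene resolution.

A signature is an ordered list of features (probes or gene symbols), each
with a direction of change in hepatic metastasis versus the paired primary
tumor.  Microarray probes map to gene symbols through a caller-supplied
multimap; a probe matching several genes (e.g. an immunoglobulin-cluster
probe) only contributes the genes for which a *gene-specific* probe exists
in a relaxed-FDR candidate list, so cross-platform gene signatures never
rest on ambiguous evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

UP = "up_in_HM"
DOWN = "down_in_HM"
_DIRECTIONS = (UP, DOWN)


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureEntry:
    feature_id: str
    direction: str
    source_probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise SignatureError(f"direction must be one of {_DIRECTIONS}")


@dataclass(frozen=True)
class Signature:
    """Ordered features with direction; ``feature_space`` is probe or gene."""

    entries: tuple[SignatureEntry, ...]
    feature_space: str = "probe"

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SignatureError(f"duplicated feature id {dup!r}")
        if self.feature_space not in ("probe", "gene"):
            raise SignatureError("feature_space must be 'probe' or 'gene'")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def direction_of(self, feature_id: str) -> str:
        for e in self.entries:
            if e.feature_id == feature_id:
                return e.direction
        raise KeyError(feature_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"feature_id": e.feature_id, "direction": e.direction,
              "source_probes": ";".join(e.source_probes)}
             for e in self.entries])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_signature(path: str | Path, feature_space: str = "gene") -> Signature:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = tuple(
        SignatureEntry(
            feature_id=r["feature_id"], direction=r["direction"],
            source_probes=tuple(p for p in r.get("source_probes", "").split(";") if p))
        for _, r in df.iterrows())
    return Signature(entries=entries, feature_space=feature_space)


def load_liver_metastasis_signature() -> Signature:
    """The published 33-gene colorectal liver-metastasis signature.

    25 genes down- and 8 up-regulated in hepatic metastases versus paired
    primary tumors, shipped with the package for validation workflows.
    """
    with resources.as_file(
            resources.files("metasig.data") / "liver_metastasis_signature_33gene.tsv"
    ) as p:
        return load_signature(p, feature_space="gene")


def read_probe_gene_map(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns probe_id, gene_symbol; one row per mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["probe_id"], []).append(r["gene_symbol"])
    return out


def probes_to_genes(sig: Signature, probe_gene_map: Mapping[str, Sequence[str]],
                    relaxed_candidates: Iterable[str]) -> Signature:
    """Collapse a probe signature onto gene symbols.

    Single-gene probes map directly.  A multi-gene probe contributes
    exactly those of its genes that possess a gene-specific (single-gene)
    probe within ``relaxed_candidates`` — a wider differential list at a
    relaxed FDR.  Genes hit by several probes collapse to one entry whose
    directions must agree.
    """
    if sig.feature_space != "probe":
        raise SignatureError("input signature must be in probe space")
    relaxed = set(relaxed_candidates)

    # gene -> set of specific probes available in the relaxed list
    specific_in_relaxed: dict[str, list[str]] = {}
    for probe in relaxed:
        genes = probe_gene_map.get(probe, [])
        if len(genes) == 1:
            specific_in_relaxed.setdefault(genes[0], []).append(probe)

    gene_dir: dict[str, str] = {}
    gene_probes: dict[str, list[str]] = {}
    order: list[str] = []
    for entry in sig.entries:
        genes = list(probe_gene_map.get(entry.feature_id, []))
        if not genes:
            warnings.warn(f"probe {entry.feature_id!r} has no gene mapping; dropped")
            continue
        if len(genes) > 1:
            resolved = [g for g in genes if g in specific_in_relaxed]
            if not resolved:
                warnings.warn(
                    f"multi-gene probe {entry.feature_id!r} has no gene with a "
                    "specific probe in the relaxed list; contributes no genes")
            genes = resolved
        for g in genes:
            if g in gene_dir:
                if gene_dir[g] != entry.direction:
                    raise SignatureError(
                        f"gene {g!r} mapped with conflicting directions by probes "
                        f"{gene_probes[g] + [entry.feature_id]}")
            else:
                gene_dir[g] = entry.direction
                order.append(g)
            if entry.feature_id not in gene_probes.setdefault(g, []):
                gene_probes[g].append(entry.feature_id)

    entries = tuple(
        SignatureEntry(feature_id=g, direction=gene_dir[g],
                       source_probes=tuple(gene_probes[g]))
        for g in order)
    return Signature(entries=entries, feature_space="gene")


def restrict_to_platform(sig: Signature, platform_features: Iterable[str]
                         ) -> Signature:
    """Intersect a signature with a platform's feature set, keeping order."""
    feats = set(platform_features)
    entries = tuple(e for e in sig.entries if e.feature_id in feats)
    if not entries:
        warnings.warn("no signature feature present on the platform")
    return Signature(entries=entries, feature_space=sig.feature_space)
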