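"""Glycan-peak harmonization and the derived-trait engine.

Plasma N-glycans separated by HILIC-UPLC are quantified as integrated
chromatogram peaks (GPs), each expressed relative to the total area — a
composition.  Cohorts differ in how many peaks their chromatography resolves,
so peaks are first *harmonized*: co-eluting original peaks are summed onto a
shared 36-peak panel.  From the harmonized panel, derived traits summarise
structural features (galactosylation, sialylation, fucosylation, branching)
through one of three compositional transforms:

``MERGE_CLR``
    The trait is the share of a glycan group in the whole composition: the
    group's peaks are merged (summed) into one part, the merged 36-part ->
    (36 - g + 1)-part composition is CLR-transformed, and the merged part's
    CLR coordinate is the trait value.
``SUBCOMP_CLR``
    As above but within a stated repertoire: the composition is first
    restricted to the repertoire's peaks and re-closed, then merge + CLR.
``RATIO_ILR``
    The trait is a balance between two disjoint groups:
    ``(1/sqrt(2)) * ln(sum(numerator) / sum(denominator))``, the isometric
    log-ratio coordinate of a 1-vs-1 balance.

The engine is definition-driven: definitions live in a CSV registry, so other
panels (e.g. a 24-peak IgG panel) can be processed by supplying an alternative
registry file.  The shipped registry and harmonization map are synthetic
stand-ins for the study's supplementary tables (see their file docstrings);
they have the documented shape (39 -> 36 peaks, 81 derived traits) and anchor
the traits discussed in the accompanying analyses (PGP37, PGP43, PGP62,
PGP109) to their published descriptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .compositional import centered_pca, closure, clr_transform, impute_min_fraction

__all__ = [
    "HarmonizationMap",
    "DerivedTraitDef",
    "load_harmonization_map",
    "load_registry",
    "default_harmonization_map",
    "default_registry",
    "harmonize",
    "total_area_normalize",
    "derive_trait",
    "original_trait_clr",
    "build_trait_matrix",
    "glycan_pca",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class HarmonizationMap:
    """Total mapping original peak -> harmonized GP label."""

    mapping: dict[str, str]

    @property
    def original_peaks(self) -> list[str]:
        return list(self.mapping)

    @property
    def harmonized_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for gp in self.mapping.values():
            seen.setdefault(gp)
        return list(seen)


@dataclass(frozen=True)
class DerivedTraitDef:
    """One derived glycan trait: a named compositional transform of GP groups."""

    name: str
    transform_class: str
    numerator: frozenset[str]
    repertoire: frozenset[str] = field(default_factory=frozenset)
    denominator: frozenset[str] = field(default_factory=frozenset)
    description: str = ""

    def __post_init__(self) -> None:
        if self.transform_class not in {"MERGE_CLR", "SUBCOMP_CLR", "RATIO_ILR"}:
            raise ValueError(f"{self.name}: unknown class {self.transform_class!r}")
        if not self.numerator:
            raise ValueError(f"{self.name}: empty numerator")
        if self.transform_class == "SUBCOMP_CLR":
            if not self.numerator <= self.repertoire:
                raise ValueError(f"{self.name}: numerator not within repertoire")
            if self.numerator == self.repertoire:
                raise ValueError(f"{self.name}: numerator equals repertoire "
                                 "(1-part composition has no CLR)")
        if self.transform_class == "RATIO_ILR":
            if not self.denominator:
                raise ValueError(f"{self.name}: ratio needs a denominator")
            if self.numerator & self.denominator:
                raise ValueError(f"{self.name}: numerator and denominator overlap")


def load_harmonization_map(path) -> HarmonizationMap:
    df = pd.read_csv(path)
    if df["original_peak"].duplicated().any():
        dup = df.loc[df["original_peak"].duplicated(), "original_peak"].iloc[0]
        raise ValueError(f"original peak {dup!r} mapped more than once")
    return HarmonizationMap(dict(zip(df["original_peak"], df["harmonized_gp"])))


def _split(cell) -> frozenset[str]:
    if pd.isna(cell) or cell == "":
        return frozenset()
    return frozenset(str(cell).split(";"))


def load_registry(path, gp_labels=None) -> list[DerivedTraitDef]:
    """Load derived-trait definitions from CSV; validate names and GP references."""
    df = pd.read_csv(path)
    defs = [
        DerivedTraitDef(
            name=r["name"],
            transform_class=r["transform_class"],
            numerator=_split(r["numerator"]),
            repertoire=_split(r.get("repertoire")),
            denominator=_split(r.get("denominator")),
            description=r.get("description", "") or "",
        )
        for r in df.to_dict("records")
    ]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate trait names in registry")
    if gp_labels is not None:
        known = set(gp_labels)
        for d in defs:
            missing = (d.numerator | d.repertoire | d.denominator) - known
            if missing:
                raise ValueError(f"{d.name}: unknown GP reference(s) {sorted(missing)}")
    return defs


def _data_path(name: str):
    return resources.files("glycomicrobe.data").joinpath(name)


def default_harmonization_map() -> HarmonizationMap:
    """Shipped synthetic 39 -> 36 plasma harmonization map."""
    with resources.as_file(_data_path("harmonization_map_synthetic.csv")) as p:
        return load_harmonization_map(p)


def default_registry(validate_against_default_map: bool = True) -> list[DerivedTraitDef]:
    """Shipped synthetic 81-trait plasma registry (PGP37..PGP117)."""
    labels = default_harmonization_map().harmonized_labels if validate_against_default_map else None
    with resources.as_file(_data_path("derived_traits_synthetic.csv")) as p:
        return load_registry(p, gp_labels=labels)


def harmonize(peaks: pd.DataFrame, hmap: HarmonizationMap) -> pd.DataFrame:
    """Sum co-eluting original peaks into harmonized GPs (total area preserved)."""
    unmapped = [c for c in peaks.columns if c not in hmap.mapping]
    if unmapped:
        raise ValueError(f"unmapped input peak(s): {unmapped}")
    out = pd.DataFrame(0.0, index=peaks.index, columns=hmap.harmonized_labels)
    for orig, gp in hmap.mapping.items():
        if orig in peaks.columns:
            out[gp] = out[gp] + peaks[orig].astype(float)
    return out


def total_area_normalize(peaks: pd.DataFrame) -> pd.DataFrame:
    """Divide each GP area by the sample's total area (rows sum to 1)."""
    return closure(peaks)


def _merged_clr_value(rel_row: np.ndarray, num_mask: np.ndarray) -> float:
    merged = rel_row[num_mask].sum()
    others = rel_row[~num_mask]
    logs = np.concatenate(([np.log(merged)], np.log(others)))
    return float(logs[0] - logs.mean())


def derive_trait(peaks: pd.DataFrame, tdef: DerivedTraitDef) -> pd.Series:
    """Compute one derived trait from a positive relative-area GP table.

    ``peaks`` must be total-area normalized with zeros already imputed
    (strictly positive); use :func:`build_trait_matrix` for the full workflow.
    """
    cols = list(peaks.columns)
    missing = (tdef.numerator | tdef.repertoire | tdef.denominator) - set(cols)
    if missing:
        raise ValueError(f"{tdef.name}: GP(s) {sorted(missing)} absent from table")
    arr = peaks.to_numpy(dtype=float)
    if np.any(arr <= 0):
        raise ValueError(f"{tdef.name}: non-positive GP values; impute zeros first")

    if tdef.transform_class == "RATIO_ILR":
        num = arr[:, [cols.index(g) for g in sorted(tdef.numerator)]].sum(axis=1)
        den = arr[:, [cols.index(g) for g in sorted(tdef.denominator)]].sum(axis=1)
        vals = np.log(num / den) / _SQRT2
        return pd.Series(vals, index=peaks.index, name=tdef.name)

    if tdef.transform_class == "SUBCOMP_CLR":
        rep = sorted(tdef.repertoire)
        sub = arr[:, [cols.index(g) for g in rep]]
        sub = sub / sub.sum(axis=1, keepdims=True)
        num_mask = np.array([g in tdef.numerator for g in rep])
    else:  # MERGE_CLR over the full composition
        if tdef.numerator >= set(cols):
            raise ValueError(f"{tdef.name}: numerator covers the whole composition")
        sub = arr / arr.sum(axis=1, keepdims=True)
        num_mask = np.array([g in tdef.numerator for g in cols])

    vals = np.array([_merged_clr_value(row, num_mask) for row in sub])
    return pd.Series(vals, index=peaks.index, name=tdef.name)


def original_trait_clr(peaks: pd.DataFrame) -> pd.DataFrame:
    """CLR transform of the harmonized GP composition (the 'original' traits)."""
    return clr_transform(peaks)


def build_trait_matrix(
    raw_peaks: pd.DataFrame,
    hmap: HarmonizationMap | None = None,
    registry: list[DerivedTraitDef] | None = None,
) -> pd.DataFrame:
    """Raw peak areas -> full trait matrix (original CLR traits + derived traits).

    Steps: harmonize, total-area normalize, impute zeros by the minimal
    positive fraction per GP, then compute CLR original traits and every
    registry trait.  With the shipped map and registry this yields 117
    columns: GP1..GP36 then PGP37..PGP117.
    """
    hmap = hmap or default_harmonization_map()
    registry = registry if registry is not None else default_registry()
    gp = harmonize(raw_peaks, hmap)
    gp = total_area_normalize(gp)
    gp = impute_min_fraction(gp)
    parts = [original_trait_clr(gp)]
    parts.append(pd.DataFrame({t.name: derive_trait(gp, t) for t in registry}))
    return pd.concat(parts, axis=1)


def glycan_pca(traits: pd.DataFrame, k: int = 10):
    """First ``k`` glycan principal components of the trait matrix.

    Returns ``(scores, loadings, variance_fractions)`` from a centered PCA
    with a deterministic sign convention (largest-|loading| positive).
    """
    return centered_pca(traits, k)
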