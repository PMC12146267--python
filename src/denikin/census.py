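"""Genomic denitrification pathway census and groundwater co-occurrence.

Classifies genomes by which of the four denitrification steps they encode
(Nar/Nap nitrate reductase, Nir nitrite reductase, Nor nitric-oxide
reductase, Nos nitrous-oxide reductase) from a genome x KEGG-Orthology
count table, summarizes the census (fraction of incomplete denitrifiers,
likely N2O producers: Nor without Nos), and derives genus presence/absence
from log10 relative abundance with threshold-based co-occurrence and
abundance-chemistry correlation.

The KO -> step mapping ships as an editable TSV (``data/ko_map.tsv``); no
online annotation is performed.  The 10-genome fixture in
``data/synthetic_toy_genomes.tsv`` is synthetic, constructed for worked
examples and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

#: canonical order of the four pathway steps
STEPS = ("Nar", "Nir", "Nor", "Nos")
#: default presence threshold on log10 relative abundance
DEFAULT_ABUNDANCE_THRESHOLD = -6.0


@dataclass
class PathwayProfile:
    """Presence/absence of the four denitrification steps in one genome."""

    genome: str
    presence: dict[str, bool]

    @property
    def complete(self) -> bool:
        return all(self.presence.get(step, False) for step in STEPS)

    @property
    def composition_class(self) -> str:
        """Subset label like ``"Nar+Nor+Nos"`` in canonical step order."""
        return "+".join(step for step in STEPS if self.presence.get(step, False))

    @property
    def likely_n2o_producer(self) -> bool:
        """Encodes Nor but not Nos: reduces NO to N2O it cannot consume."""
        return self.presence.get("Nor", False) and not self.presence.get("Nos", False)


def load_ko_map(path=None) -> dict[str, set[str]]:
    """KO -> pathway-step mapping as {step: set of KO ids}.

    Defaults to the shipped TSV; both Nar and Nap orthologs satisfy the
    nitrate-reduction step.
    """
    if path is None:
        ref = resources.files("denikin.data").joinpath("ko_map.tsv")
        with ref.open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    ko_map = {step: set(df.loc[df["step"] == step, "ko"]) for step in df["step"].unique()}
    return ko_map


def load_toy_genomes() -> pd.DataFrame:
    """The shipped synthetic 10-genome KO count fixture (index = genome)."""
    ref = resources.files("denikin.data").joinpath("synthetic_toy_genomes.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="genome")


def classify_pathway(
    ko_table: pd.DataFrame, ko_map: dict[str, set[str]] | None = None
) -> list[PathwayProfile]:
    """Pathway profiles from a genome x KO count table.

    A step is present iff at least one of its mapped KOs has a count >= 1.
    Genomes with zero denitrification KOs are excluded from the output.
    Duplicate KO columns and column order do not affect the result.
    """
    if ko_map is None:
        ko_map = load_ko_map()
    for step in STEPS:
        if not ko_map.get(step):
            raise ValueError(f"KO map has no entries for step {step!r}")
    profiles = []
    for genome, row in ko_table.iterrows():
        presence = {}
        any_gene = False
        for step in STEPS:
            cols = [c for c in ko_table.columns if c in ko_map[step]]
            present = bool((row[cols] >= 1).any()) if cols else False
            presence[step] = present
            any_gene = any_gene or present
        if any_gene:
            profiles.append(PathwayProfile(genome=str(genome), presence=presence))
    return profiles


def census_summary(profiles: list[PathwayProfile]) -> dict:
    """Census fractions and composition-class histogram.

    ``frac_n2o_producers`` counts genomes with Nor but no Nos among the
    *incomplete* denitrifiers; the denominator choice is recorded in the
    metadata so either convention can be reproduced.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    n = len(profiles)
    incomplete = [p for p in profiles if not p.complete]
    producers = [p for p in incomplete if p.likely_n2o_producer]
    histogram: dict[str, int] = {}
    for p in profiles:
        histogram[p.composition_class] = histogram.get(p.composition_class, 0) + 1
    return {
        "n_genomes": n,
        "frac_incomplete": len(incomplete) / n,
        "frac_n2o_producers": (len(producers) / len(incomplete)) if incomplete else 0.0,
        "class_histogram": histogram,
        "metadata": {
            "n2o_producer_rule": "Nor present and Nos absent",
            "n2o_producer_denominator": "incomplete",
        },
    }


@dataclass
class PresenceMatrix:
    """Boolean samples x genera presence with the derivation threshold."""

    values: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        self.values = self.values.astype(bool)


def presence_threshold(
    log_rel_abundance: pd.DataFrame, threshold: float = DEFAULT_ABUNDANCE_THRESHOLD
) -> PresenceMatrix:
    """Presence iff log10 relative abundance is strictly above the threshold.

    The default threshold of -6 separates the two peaks of the typically
    bimodal log-abundance distribution.  Values exactly at the threshold
    count as absent (strict inequality); missing values are absent.
    """
    df = log_rel_abundance.copy()
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            first = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(f"non-numeric entry at sample {first!r}, genus {col!r}")
        df[col] = coerced
    present = df.gt(threshold) & df.notna()
    return PresenceMatrix(values=present, threshold=threshold)


def cooccurrence(pm: PresenceMatrix, focal: str) -> pd.Series:
    """Per-genus co-occurrence frequency with a focal genus.

    For each other genus g: #(samples with focal and g) / #(samples with
    focal).  Undefined (error) when the focal genus is absent everywhere.
    """
    if focal not in pm.values.columns:
        raise KeyError(focal)
    focal_mask = pm.values[focal]
    n_focal = int(focal_mask.sum())
    if n_focal == 0:
        raise ValueError(f"focal genus {focal!r} is absent from every sample")
    others = [c for c in pm.values.columns if c != focal]
    freq = pm.values.loc[focal_mask, others].sum(axis=0) / n_focal
    return freq.astype(float)


def correlate_chemistry(abundance, chemistry) -> dict:
    """Pearson and Spearman correlation between abundance and a chemistry series.

    Pairwise-complete: rows where either value is missing are dropped.
    Zero variance in either series leaves the coefficients undefined
    (NaN) with a ``zero_variance`` flag.
    """
    a = pd.Series(abundance, dtype=float)
    c = pd.Series(chemistry, dtype=float)
    mask = a.notna() & c.notna()
    a, c = a[mask], c[mask]
    if len(a) < 3:
        raise ValueError("need at least 3 paired finite observations")
    out: dict = {"n": int(len(a)), "flags": []}
    if a.std() == 0 or c.std() == 0:
        out.update(
            pearson_r=np.nan, pearson_p=np.nan, spearman_r=np.nan, spearman_p=np.nan
        )
        out["flags"].append("zero_variance")
        return out
    pr = stats.pearsonr(a, c)
    sr = stats.spearmanr(a, c)
    out.update(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )
    return out


def profiles_to_frame(profiles: list[PathwayProfile]) -> pd.DataFrame:
    """Tidy profiles table (one row per genome)."""
    rows = []
    for p in profiles:
        row = {"genome": p.genome, **{step: p.presence.get(step, False) for step in STEPS}}
        row["composition_class"] = p.composition_class
        row["complete"] = p.complete
        row["likely_n2o_producer"] = p.likely_n2o_producer
        rows.append(row)
    return pd.DataFrame(rows)
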