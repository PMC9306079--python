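"""Amino-acid and B-vitamin prototrophy profiles and community
complementarity.

A genome is *prototrophic* for a compound when its biosynthesis pathway is
called present under the pathway-completeness heuristic, *auxotrophic*
otherwise. The compound panel is the 20 proteinogenic amino acids (each as
its own pathway, including the near-trivial glutamate/aspartate family) and
the 8 B-vitamins (B1, B2, B3, B5, B6, B7, B9, B12). For every compound the
community splits into providers (pathway present) and dependents (pathway
absent); compounds without any provider mark community-wide auxotrophy —
growth factors that must come from outside the community.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import Community, GenomeRecord
from .pathway_engine import PathwayDef, call_pathway, pathway_matrix

__all__ = [
    "TrophyProfile",
    "trophy_profile",
    "community_profiles",
    "providers",
    "complementarity_report",
    "prototrophy_correlations",
    "profiles_to_frames",
]


@dataclass(frozen=True)
class TrophyProfile:
    """Per-genome presence vectors over amino-acid and vitamin pathways."""

    genome_id: str
    aa_present: Mapping[str, bool]
    vit_present: Mapping[str, bool]

    @property
    def aa_fraction(self) -> float:
        if not self.aa_present:
            return float("nan")
        return float(np.mean([bool(v) for v in self.aa_present.values()]))

    @property
    def vit_fraction(self) -> float:
        if not self.vit_present:
            return float("nan")
        return float(np.mean([bool(v) for v in self.vit_present.values()]))

    @property
    def fully_aa_prototrophic(self) -> bool:
        return all(self.aa_present.values())

    @property
    def fully_vit_prototrophic(self) -> bool:
        return all(self.vit_present.values())


def _split_defs(defs: Sequence[PathwayDef]):
    aa = [d for d in defs if d.category == "amino_acid"]
    vit = [d for d in defs if d.category == "b_vitamin"]
    return aa, vit


def trophy_profile(
    genome: GenomeRecord, defs: Sequence[PathwayDef], allowed_missing: int = 1
) -> TrophyProfile:
    """Fill a genome's prototrophy vectors from pathway calls."""
    aa_defs, vit_defs = _split_defs(defs)
    aa = {
        d.pathway_id: call_pathway(d, genome.genes, allowed_missing).present
        for d in aa_defs
    }
    vit = {
        d.pathway_id: call_pathway(d, genome.genes, allowed_missing).present
        for d in vit_defs
    }
    return TrophyProfile(genome_id=genome.genome_id, aa_present=aa, vit_present=vit)


def community_profiles(
    community: Community, defs: Sequence[PathwayDef], allowed_missing: int = 1
) -> dict[str, TrophyProfile]:
    return {
        g.genome_id: trophy_profile(g, defs, allowed_missing) for g in community
    }


def providers(
    profiles: Mapping[str, TrophyProfile], compound: str
) -> list[str]:
    """Genomes whose biosynthesis pathway for ``compound`` is present, in
    community order. Unknown compounds raise with the valid vocabulary."""
    profile_list = list(profiles.values())
    if not profile_list:
        return []
    valid = set(profile_list[0].aa_present) | set(profile_list[0].vit_present)
    if compound not in valid:
        raise KeyError(
            f"unknown compound {compound!r}; valid ids: {sorted(valid)}"
        )
    out = []
    for gid, prof in profiles.items():
        vec = prof.aa_present if compound in prof.aa_present else prof.vit_present
        if vec[compound]:
            out.append(gid)
    return out


def complementarity_report(
    profiles: Mapping[str, TrophyProfile]
) -> pd.DataFrame:
    """Per compound: provider set, dependent set, and the community-wide
    auxotrophy flag (no provider at all). Providers and dependents partition
    the community for every compound."""
    profile_list = list(profiles.values())
    compounds: list[str] = []
    if profile_list:
        compounds = list(profile_list[0].aa_present) + list(profile_list[0].vit_present)
    rows = []
    for compound in compounds:
        prov = providers(profiles, compound)
        dep = [gid for gid in profiles if gid not in set(prov)]
        rows.append(
            {
                "compound": compound,
                "n_providers": len(prov),
                "n_dependents": len(dep),
                "providers": ",".join(prov),
                "dependents": ",".join(dep),
                "community_wide_auxotrophy": len(prov) == 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "n_providers",
            "n_dependents",
            "providers",
            "dependents",
            "community_wide_auxotrophy",
        ],
    )


def prototrophy_correlations(
    community: Community, profiles: Mapping[str, TrophyProfile]
) -> dict[str, float]:
    """Pearson correlation of the amino-acid prototrophy fraction with MAG
    completeness and with MAG abundance. Reported as-is; no threshold is
    applied."""
    fractions, completeness, abundance = [], [], []
    for g in community:
        prof = profiles.get(g.genome_id)
        if prof is None:
            continue
        fractions.append(prof.aa_fraction)
        completeness.append(g.completeness)
        abundance.append(g.abundance if g.abundance is not None else np.nan)
    out: dict[str, float] = {}
    frac = np.asarray(fractions, dtype=float)
    comp = np.asarray(completeness, dtype=float)
    abun = np.asarray(abundance, dtype=float)
    if len(frac) >= 3 and np.std(frac) > 0 and np.std(comp) > 0:
        out["aa_prototrophy_vs_completeness"] = float(stats.pearsonr(frac, comp)[0])
    else:
        out["aa_prototrophy_vs_completeness"] = float("nan")
    mask = ~np.isnan(abun)
    if mask.sum() >= 3 and np.std(frac[mask]) > 0 and np.std(abun[mask]) > 0:
        out["aa_prototrophy_vs_abundance"] = float(
            stats.pearsonr(frac[mask], abun[mask])[0]
        )
    else:
        out["aa_prototrophy_vs_abundance"] = float("nan")
    return out


def profiles_to_frames(
    profiles: Mapping[str, TrophyProfile]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render profiles as (genomes x amino acids, genomes x vitamins) 0/1 tables."""
    gids = list(profiles)
    if not gids:
        empty = pd.DataFrame(index=pd.Index([], name="genome_id"))
        return empty, empty.copy()
    aa_ids = list(profiles[gids[0]].aa_present)
    vit_ids = list(profiles[gids[0]].vit_present)
    aa = pd.DataFrame(
        [[int(profiles[g].aa_present[a]) for a in aa_ids] for g in gids],
        index=pd.Index(gids, name="genome_id"),
        columns=aa_ids,
    )
    vit = pd.DataFrame(
        [[int(profiles[g].vit_present[v]) for v in vit_ids] for g in gids],
        index=pd.Index(gids, name="genome_id"),
        columns=vit_ids,
    )
    return aa, vit
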