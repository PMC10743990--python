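"""Virtual-screening funnel: consensus scoring, novelty filter, clustering,
and PAINS alerts.

The funnel retains library compounds with CS >= 0.8 (configurable), removes
those with Tanimoto >= 0.40 to any training compound (Morgan/2048), groups
the survivors by Butina sphere-exclusion clustering on the RDKit fingerprint
at similarity 0.70, flags the highest-CS member of each cluster as its
representative, and annotates pan-assay interference (PAINS) alerts from the
openly published A/B/C SMARTS families.  Each stage's output is a subset of
its input and stage counts reconcile exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import FilterCatalog
from rdkit.ML.Cluster import Butina

from .consensus import ConsensusModel
from .curation import LabeledDataset, StandardizedCompound
from .representations import featurize, tanimoto_matrix

CS_CUTOFF = 0.8
NOVELTY_MAX_SIM = 0.40
CLUSTER_SIM_CUTOFF = 0.70


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningHit:
    compound: StandardizedCompound
    cs: float
    member_ps: tuple[float, ...] = ()
    max_train_similarity: float = float("nan")
    cluster_id: int = -1
    is_cluster_representative: bool = False
    pains_alerts: tuple[str, ...] = ()


@dataclass
class FunnelResult:
    hits: list[ScreeningHit]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def selection(self) -> list[ScreeningHit]:
        """Final pick: alert-free cluster representatives."""
        return [
            h
            for h in self.hits
            if h.is_cluster_representative and not h.pains_alerts
        ]


def screen(
    consensus: ConsensusModel,
    library: Sequence[StandardizedCompound],
    cs_cutoff: float = CS_CUTOFF,
    chunk_size: int = 2000,
) -> list[ScreeningHit]:
    """Score a standardized library and keep compounds with CS >= cutoff.

    The library is processed in chunks so memory stays bounded for large
    collections.
    """
    if not 0.5 <= cs_cutoff <= 1.0:
        raise ScreeningError("cs_cutoff must lie in [0.5, 1]")
    library = list(library)
    if not library:
        warnings.warn("empty screening library")
        return []
    hits: list[ScreeningHit] = []
    for start in range(0, len(library), chunk_size):
        chunk = library[start : start + chunk_size]
        feats = {kind: featurize(chunk, kind).data for kind in consensus.kinds}
        ps = consensus.member_ps(feats)
        cs = ps.mean(axis=1)
        for compound, row, score in zip(chunk, ps, cs):
            if score >= cs_cutoff:
                hits.append(
                    ScreeningHit(
                        compound=compound,
                        cs=float(score),
                        member_ps=tuple(float(p) for p in row),
                    )
                )
    return hits


def novelty_filter(
    hits: Sequence[ScreeningHit],
    train: LabeledDataset,
    max_sim: float = NOVELTY_MAX_SIM,
) -> list[ScreeningHit]:
    """Drop hits with Tanimoto >= max_sim (Morgan/2048) to any training
    compound; annotate the surviving hits with their nearest-neighbor
    similarity."""
    if len(train) == 0:
        raise ScreeningError("training set must be non-empty")
    hits = list(hits)
    if not hits:
        return []
    train_fp = featurize([c.compound for c in train.compounds], "morgan").data
    hit_fp = featurize([h.compound for h in hits], "morgan").data
    max_sims = tanimoto_matrix(hit_fp, train_fp).max(axis=1)
    return [
        replace(h, max_train_similarity=float(s))
        for h, s in zip(hits, max_sims)
        if s < max_sim
    ]


def cluster_hits(
    hits: Sequence[ScreeningHit], sim_cutoff: float = CLUSTER_SIM_CUTOFF
) -> list[ScreeningHit]:
    """Butina sphere-exclusion clustering on the RDKit fingerprint.

    Two hits fall in one sphere when their Tanimoto similarity is >= the
    cutoff.  Within each cluster the highest-CS member is flagged as the
    representative; CS ties go to the lexicographically smallest compound id.
    Deterministic under fixed input order (no randomness involved).
    """
    hits = list(hits)
    if not hits:
        return []
    fps = featurize([h.compound for h in hits], "rdkit").data
    n = len(hits)
    sim = tanimoto_matrix(fps, fps)
    # Butina wants a condensed lower-triangle distance list
    dists = [1.0 - sim[i, j] for i in range(1, n) for j in range(i)]
    clusters = Butina.ClusterData(
        dists, n, distThresh=1.0 - sim_cutoff, isDistData=True
    )
    out: list[ScreeningHit] = [None] * n  # type: ignore[list-item]
    for cluster_id, member_ids in enumerate(clusters):
        rep = min(
            member_ids,
            key=lambda i: (-hits[i].cs, hits[i].compound.compound_id),
        )
        for i in member_ids:
            out[i] = replace(
                hits[i],
                cluster_id=cluster_id,
                is_cluster_representative=(i == rep),
            )
    return out


@lru_cache(maxsize=1)
def _pains_catalog() -> FilterCatalog.FilterCatalog:
    params = FilterCatalog.FilterCatalogParams()
    for fam in (
        FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS_A,
        FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS_B,
        FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS_C,
    ):
        params.AddCatalog(fam)
    return FilterCatalog.FilterCatalog(params)


def pains_alerts(smiles: str) -> tuple[str, ...]:
    """Names of PAINS A/B/C substructure alerts matched by a SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ()
    matches = _pains_catalog().GetMatches(mol)
    return tuple(m.GetDescription() for m in matches)


def pains_filter(hits: Sequence[ScreeningHit]) -> list[ScreeningHit]:
    """Annotate every hit with its PAINS alerts.

    Alerted compounds stay in the returned (annotated) table; the funnel's
    final selection excludes them via :attr:`FunnelResult.selection`.
    """
    return [
        replace(h, pains_alerts=pains_alerts(h.compound.smiles_std)) for h in hits
    ]


def run_funnel(
    consensus: ConsensusModel,
    library: Sequence[StandardizedCompound],
    train: LabeledDataset,
    cs_cutoff: float = CS_CUTOFF,
    novelty_max_sim: float = NOVELTY_MAX_SIM,
    cluster_sim_cutoff: float = CLUSTER_SIM_CUTOFF,
) -> FunnelResult:
    """Full hit funnel: CS filter -> novelty filter -> clustering -> PAINS."""
    library = list(library)
    retained = screen(consensus, library, cs_cutoff=cs_cutoff)
    novel = novelty_filter(retained, train, max_sim=novelty_max_sim)
    clustered = cluster_hits(novel, sim_cutoff=cluster_sim_cutoff) if novel else []
    annotated = pains_filter(clustered)
    n_clusters = len({h.cluster_id for h in annotated}) if annotated else 0
    result = FunnelResult(
        hits=annotated,
        counts={
            "library": len(library),
            "cs_filter": len(retained),
            "novelty_filter": len(novel),
            "clusters": n_clusters,
            "representatives": sum(1 for h in annotated if h.is_cluster_representative),
            "final_selection": 0,
        },
    )
    result.counts["final_selection"] = len(result.selection)
    return result
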