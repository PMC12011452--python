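"""End-to-end analysis: from input tables to the full result bundle.

``run_pipeline`` ties the stages together in the order a diet-metabarcoding
study reports them: per-sample alpha diversity and rarefaction at the OTU
level, seasonal per-group RRA profiles with top-N and growth-form tables,
shared-OTU Venn partitions, Bray-Curtis distances with NMDS ordination,
intra/intergroup distance comparison and a UPGMA dendrogram of the group
profiles, and finally the trophic-niche table (Levins B, Hurlbert Ba,
Pianka Q, dietary Shannon diversity) per species and season.

Every stochastic stage draws from its own stream spawned from the master
seed, so toggling one stage does not perturb another and the whole bundle
is byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    bray_curtis_matrix,
    intergroup_distances,
    nmds,
    shared_otu_counts,
    upgma,
)
from .diversity import alpha_diversity_table, kruskal_wallis, rarefaction_curve
from .io import (
    OtuTable,
    SampleRecord,
    Season,
    Species,
    metadata_index,
    read_growth_forms,
    read_metadata,
    read_otu_table,
    read_taxonomy,
)
from .niche import niche_result, overlap_matrix
from .profiles import (
    group_profiles,
    growth_form_percentages,
    resolve_taxa,
    to_rra,
    top_n_taxa,
)
from .diversity import shannon

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    otu_table: Path
    metadata: Path
    taxonomy: Path
    out_dir: Path
    seed: int
    growth_forms: Path | None = None
    rank: str = "genus"
    pooling: str = "mean_rra"
    drop_unassigned: bool = True
    orientation: str = "samples_as_rows"
    top_n: int = 10
    overlap_threshold: float = 0.6
    rarefaction_fractions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)
    rarefaction_replicates: int = 10
    nmds_restarts: int = 20
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-6
    skip_nmds: bool = False
    skip_rarefaction: bool = False
    plots: bool = False

    def to_jsonable(self) -> dict:
        d = {}
        for k, v in vars(self).items():
            if isinstance(v, Path):
                v = str(v)
            if isinstance(v, tuple):
                v = list(v)
            d[k] = v
        return d


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)
    rarefaction_seed, nmds_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(2)
    )

    table = _stage("read_otu_table")(read_otu_table)(config.otu_table, config.orientation)
    metadata = _stage("read_metadata")(read_metadata)(config.metadata)
    taxonomy = _stage("read_taxonomy")(read_taxonomy)(config.taxonomy)
    gmap = None
    if config.growth_forms is not None:
        gmap = _stage("read_growth_forms")(read_growth_forms)(config.growth_forms)

    meta_idx = metadata_index(metadata)
    missing = [s for s in table.sample_ids if s not in meta_idx]
    if missing:
        raise PipelineError(
            f"stage 'metadata' failed: samples without metadata: {missing[:5]}"
        )
    outputs: list[Path] = []

    # --- alpha diversity (OTU level, unassigned included) ------------------
    alpha = _stage("alpha_diversity")(alpha_diversity_table)(table)
    alpha_path = out / "alpha_diversity.tsv"
    _write_tsv(alpha, alpha_path, index=True)
    outputs.append(alpha_path)

    # Kruskal-Wallis across species within each season, per index.
    kw_rows = []
    for season in Season:
        season_samples = {
            sp: [s for s in table.sample_ids
                 if meta_idx[s].season == season and meta_idx[s].species == sp]
            for sp in Species
        }
        groups = {sp: ids for sp, ids in season_samples.items() if ids}
        if len(groups) < 2:
            continue
        for index in ("observed_otus", "chao1", "shannon", "simpson", "pielou"):
            vals = [alpha.loc[ids, index].to_numpy() for ids in groups.values()]
            h, p = kruskal_wallis(vals)
            kw_rows.append((season.value, index, h, p))
    kw_path = out / "alpha_kruskal_wallis.tsv"
    _write_tsv(
        pd.DataFrame(kw_rows, columns=["season", "index", "H", "p"]), kw_path
    )
    outputs.append(kw_path)

    # --- rarefaction --------------------------------------------------------
    if not config.skip_rarefaction:
        rows = []
        for i, sid in enumerate(table.sample_ids):
            total = int(table.counts[i].sum())
            depths = sorted({max(1, int(round(f * total))) for f in config.rarefaction_fractions})
            curve = _stage("rarefaction")(rarefaction_curve)(
                sid,
                table.counts[i],
                depths,
                n_replicates=config.rarefaction_replicates,
                index="shannon",
                seed=rarefaction_seed + i,
            )
            rows.extend((sid, d, v) for d, v in zip(curve.depths, curve.values))
        rare_path = out / "rarefaction.tsv"
        _write_tsv(
            pd.DataFrame(rows, columns=["sample_id", "depth", "median_shannon"]),
            rare_path,
        )
        outputs.append(rare_path)

    # --- diet profiles ------------------------------------------------------
    resolved = _stage("resolve_taxa")(resolve_taxa)(taxonomy, config.rank)
    profiles = _stage("group_profiles")(group_profiles)(
        table, metadata, resolved, config.rank,
        method=config.pooling, drop_unassigned=config.drop_unassigned,
    )
    prof_rows = [
        (sp.value, se.value, config.rank, taxon, prop, prof.n_samples)
        for (sp, se), prof in profiles.items()
        for taxon, prop in zip(prof.taxa, prof.proportions)
    ]
    prof_path = out / "group_profiles.tsv"
    _write_tsv(
        pd.DataFrame(
            prof_rows,
            columns=["species", "season", "rank", "taxon", "proportion", "n_samples"],
        ),
        prof_path,
    )
    outputs.append(prof_path)

    top_rows = []
    for (sp, se), prof in profiles.items():
        sub = top_n_taxa(prof, config.top_n)
        for rank_pos, row in enumerate(sub.itertuples(index=False), start=1):
            top_rows.append((sp.value, se.value, rank_pos, row.taxon, row.proportion))
    top_path = out / f"top{config.top_n}_taxa.tsv"
    _write_tsv(
        pd.DataFrame(
            top_rows, columns=["species", "season", "position", "taxon", "proportion"]
        ),
        top_path,
    )
    outputs.append(top_path)

    if gmap is not None:
        gf_rows = []
        for (sp, se), prof in profiles.items():
            pct = growth_form_percentages(prof, gmap)
            gf_rows.append((sp.value, se.value, pct["herb"], pct["shrub"], pct["arbor"], pct["unknown"]))
        gf_path = out / "growth_form_composition.tsv"
        _write_tsv(
            pd.DataFrame(
                gf_rows, columns=["species", "season", "herb", "shrub", "arbor", "unknown"]
            ),
            gf_path,
        )
        outputs.append(gf_path)

    # --- shared OTUs (Venn, assigned OTUs only) ----------------------------
    assigned = {o for o, label in resolved.items() if label is not None}
    venn_frames = []
    seasons_present = sorted({meta_idx[s].season for s in table.sample_ids}, key=lambda s: s.value)
    for season in seasons_present:
        species_present = {meta_idx[s].species for s in table.sample_ids if meta_idx[s].season == season}
        if len(species_present) < 2:
            continue
        summary = _stage("shared_otus")(shared_otu_counts)(
            table, metadata, season, otu_subset=assigned
        )
        venn_frames.append(summary.to_dataframe())
    if venn_frames:
        venn_path = out / "venn_shared_otus.tsv"
        _write_tsv(pd.concat(venn_frames, ignore_index=True), venn_path)
        outputs.append(venn_path)

    # --- community structure ------------------------------------------------
    sample_rras = _stage("sample_rra")(to_rra)(
        table, {o: o for o in table.otu_ids}, drop_unassigned=False
    )  # OTU-level RRA: identity mapping keeps OTUs as categories
    rra_matrix = np.vstack([r.as_series().reindex(table.otu_ids, fill_value=0.0).to_numpy() for r in sample_rras])
    dm = _stage("bray_curtis")(bray_curtis_matrix)(rra_matrix, table.sample_ids)
    dm_path = out / "bray_curtis.tsv"
    _write_tsv(dm.to_dataframe(), dm_path, index=True)
    outputs.append(dm_path)

    labels = {s: f"{meta_idx[s].species.value}" for s in table.sample_ids}
    inter = _stage("intergroup_distances")(intergroup_distances)(dm, labels)
    inter_path = out / "intergroup_distances.tsv"
    _write_tsv(inter.summary(), inter_path)
    outputs.append(inter_path)

    ordination = None
    if not config.skip_nmds:
        ordination = _stage("nmds")(nmds)(
            dm,
            dims=2,
            n_restarts=config.nmds_restarts,
            max_iter=config.nmds_max_iter,
            tol=config.nmds_tol,
            seed=nmds_seed,
        )
        coords = ordination.to_dataframe()
        coords["species"] = [meta_idx[s].species.value for s in coords.index]
        coords["season"] = [meta_idx[s].season.value for s in coords.index]
        coords["stress"] = ordination.stress
        nmds_path = out / "nmds_coordinates.tsv"
        _write_tsv(coords, nmds_path, index=True)
        outputs.append(nmds_path)

    # UPGMA over the pooled group profiles (12 leaves).
    union = sorted({t for prof in profiles.values() for t in prof.taxa})
    group_ids = [f"{sp.value}:{se.value}" for (sp, se) in profiles]
    group_matrix = np.vstack(
        [prof.as_series().reindex(union, fill_value=0.0).to_numpy() for prof in profiles.values()]
    )
    gdm = bray_curtis_matrix(group_matrix, group_ids)
    tree = _stage("upgma")(upgma)(gdm)
    tree_path = out / "upgma_groups.nwk"
    tree_path.write_text(tree.to_newick() + "\n", encoding="utf-8")
    outputs.append(tree_path)

    # --- niche metrics ------------------------------------------------------
    breadth_rows = []
    for (sp, se), prof in profiles.items():
        res = niche_result(prof)
        breadth_rows.append(
            (se.value, sp.value, res.B, res.S, res.Ba, shannon(prof.proportions))
        )
    breadth_path = out / "niche_breadth.tsv"
    _write_tsv(
        pd.DataFrame(
            breadth_rows,
            columns=["season", "species", "B", "S", "Ba", "dietary_shannon"],
        ),
        breadth_path,
    )
    outputs.append(breadth_path)

    overlap_rows = []
    for season in seasons_present:
        season_profiles = [prof for (sp, se), prof in profiles.items() if se == season]
        if len(season_profiles) < 2:
            continue
        om = _stage("overlap_matrix")(overlap_matrix)(
            season_profiles, threshold=config.overlap_threshold
        )
        for i, a in enumerate(om.species):
            for j, b in enumerate(om.species):
                if j <= i:
                    continue
                overlap_rows.append(
                    (season.value, a.value, b.value, om.Q[i, j], bool(om.significant[i, j]))
                )
    overlap_path = out / "niche_overlap.tsv"
    _write_tsv(
        pd.DataFrame(
            overlap_rows,
            columns=["season", "species_j", "species_k", "Q", "significant"],
        ),
        overlap_path,
    )
    outputs.append(overlap_path)

    if config.plots:
        from . import plotting

        if ordination is not None:
            outputs.append(
                plotting.plot_nmds(ordination, labels, out / "nmds.svg")
            )
        if not config.skip_rarefaction:
            outputs.append(
                plotting.plot_rarefaction(
                    pd.read_csv(out / "rarefaction.tsv", sep="\t"), out / "rarefaction.svg"
                )
            )

    manifest = {
        "package": "dietniche",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
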