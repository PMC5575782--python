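"""End-to-end orchestration: read inputs, merge profiles, build MAPs,
compute features, score, run enrichment/crosstalk analyses and project
scores onto structure, writing deterministic TSV outputs plus a run
manifest.

Stages that lack their optional inputs (regions, structure) are skipped
with a logged warning rather than an error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .enrichment import (
    candidate_positions,
    conservation_comparison,
    enrichment_fold,
    enrichment_report,
)
from .features import compute_features, crosstalk_pairs, feature_table
from .io import (
    AnalysisConfig,
    Alignment,
    PTMType,
    RegionScope,
    ValidationError,
    file_digest,
    read_alignment,
    read_ptm_table,
    read_regions,
)
from .map_builder import build_maps, build_residue_maps, profile_align
from .scoring import bin_scores, rank_maps, rank_table, score_maps
from .structure import (
    InterfaceSet,
    detect_interface,
    map_structure_to_alignment,
    project_scores,
    read_structure,
)

log = logging.getLogger("ptmhotspots")

_RANK_COLUMNS = [
    "rank", "column", "IS", "bin", "PC", "CPC", "PRC", "NKC", "PPI",
    "member_ptms",
]
_FEATURE_COLUMNS = [
    "column", "PAC", "TRC", "membership", "PC", "CPC", "NC", "NKC", "KF",
    "PPI", "PRC", "member_ptms",
]


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]  # path -> sha256
    outputs: list[str]
    version: str
    seed: int

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "version": self.version,
                    "seed": self.seed,
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
            + "\n"
        )


@dataclass
class PipelineResult:
    alignment: Alignment
    maps: list
    scored: list
    outputs: dict[str, Path] = field(default_factory=dict)
    enrichment: Optional[pd.DataFrame] = None
    conservation: Optional[dict] = None


def _write_tsv(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    if df.empty:
        df = pd.DataFrame(columns=columns)
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(
    config: AnalysisConfig,
    alignment_path: str | Path,
    ptm_paths: Sequence[str | Path],
    out_dir: str | Path,
    query_ids: Optional[Sequence[str]] = None,
    family_alignment_path: Optional[str | Path] = None,
    regions_path: Optional[str | Path] = None,
    structure_path: Optional[str | Path] = None,
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
    chain_member: Optional[str] = None,
) -> PipelineResult:
    """Run every stage for which inputs are available.

    *alignment_path* holds the focal (query) sub-family alignment. When
    *family_alignment_path* is given the two are merged by the
    profile-to-profile aligner and downstream stages use the merged
    alignment. *chain_member* names the family member represented by
    *chain_a* of the structure (defaults to the first query row).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, Path] = {}

    aln = read_alignment(alignment_path)
    for row in aln.rows:
        row.is_query = True
    if query_ids:
        for row in aln.rows:
            row.is_query = row.seq_id in set(query_ids)
    inputs[str(alignment_path)] = file_digest(alignment_path)

    if family_alignment_path is not None:
        family = read_alignment(family_alignment_path)
        inputs[str(family_alignment_path)] = file_digest(family_alignment_path)
        log.info(
            "merging %d query rows with %d family rows",
            len(aln.rows),
            len(family.rows),
        )
        from .map_builder import load_matrix

        aln = profile_align(
            aln,
            family,
            matrix=load_matrix(config.matrix_name),
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )

    rmaps = build_residue_maps(aln)

    records = []
    for path in ptm_paths:
        records.extend(read_ptm_table(path, aln))
        inputs[str(path)] = file_digest(path)
    if not records:
        log.warning("no PTM records: rank table will be empty")
    maps = build_maps(records, rmaps)
    log.info("%d PTM records grouped into %d MAPs", len(records), len(maps))

    # structure / interface stage
    interfaces: list[InterfaceSet] = []
    mapping: dict[int, int] = {}
    struct_chain = None
    if structure_path is not None and chain_a and chain_b:
        inputs[str(structure_path)] = file_digest(structure_path)
        struct_chain = read_structure(structure_path, chain_a)
        partner = read_structure(structure_path, chain_b)
        iface_a, _ = detect_interface(
            struct_chain, partner, cutoff=config.interface_cutoff
        )
        member_id = chain_member or (
            aln.query_rows()[0].seq_id if aln.query_rows() else aln.ids[0]
        )
        member = aln.row(member_id)
        mapping = map_structure_to_alignment(
            struct_chain,
            member,
            rmaps[member_id],
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        iface_columns = {
            mapping[r] for r in iface_a.residue_positions if r in mapping
        }
        natives = {rmaps[member_id].to_native(c) for c in iface_columns}
        interfaces = [InterfaceSet(member_id, natives)]
        log.info(
            "interface: %d residues of chain %s within %.1f A of chain %s",
            len(iface_a.residue_positions),
            chain_a,
            config.interface_cutoff,
            chain_b,
        )
    elif structure_path is not None:
        log.warning("structure given without both chain ids; skipping interfaces")

    compute_features(
        aln, maps, rmaps, interfaces=interfaces, window=config.window, scope="all"
    )
    scored = rank_maps(score_maps(maps, config.weights, nkc_mode=config.nkc_mode))
    bin_scores(scored, config.n_bins)

    features_path = out / "features.tsv"
    _write_tsv(feature_table(maps) if maps else pd.DataFrame(), _FEATURE_COLUMNS, features_path)
    outputs["features"] = features_path
    ranks_path = out / "ranks.tsv"
    _write_tsv(rank_table(scored) if scored else pd.DataFrame(), _RANK_COLUMNS, ranks_path)
    outputs["ranks"] = ranks_path

    # enrichment stage
    enrich_df = None
    conservation = None
    if regions_path is not None:
        inputs[str(regions_path)] = file_digest(regions_path)
        regions = read_regions(regions_path, aln)
        scopes = {
            r.protein_id: r
            for r in regions
            if r.scope is RegionScope.native and r.name == "cytoplasmic"
        }
        acceptors = "STY" if config.include_tyrosine_candidates else "ST"
        results = []
        for region in regions:
            if region.scope is not RegionScope.native or region.name == "cytoplasmic":
                continue
            member = aln.row(region.protein_id)
            scope_region = scopes.get(region.protein_id)
            cands = candidate_positions(member, acceptors, scope_region)
            sites = [
                r
                for r in records
                if r.protein_id == region.protein_id
                and r.ptm_type is PTMType.phosphorylation
                and r.native_pos in set(cands)
            ]
            results.append(enrichment_fold(sites, cands, region))
        if results:
            enrich_df = enrichment_report(results)
            enrich_path = out / "enrichment.tsv"
            enrich_df.to_csv(enrich_path, sep="\t", index=False)
            outputs["enrichment"] = enrich_path
        aln_regions = [r for r in regions if r.scope is RegionScope.alignment]
        site_columns = {
            m.column
            for m in maps
            if any(
                p.ptm_type is PTMType.phosphorylation
                and p.protein_id in {q.seq_id for q in aln.query_rows()}
                for p in m.ptms
            )
        }
        if site_columns and aln.query_rows():
            comp_region = aln_regions[0] if aln_regions else None
            comp = conservation_comparison(
                aln, site_columns, scope="query", region=comp_region
            )
            conservation = comp._asdict()
            cons_path = out / "conservation.tsv"
            pd.DataFrame([conservation]).to_csv(cons_path, sep="\t", index=False)
            outputs["conservation"] = cons_path
    else:
        log.warning("no region annotations; skipping enrichment stage")

    # crosstalk
    pairs = crosstalk_pairs(records, window=config.crosstalk_window)
    crosstalk_path = out / "crosstalk.tsv"
    pd.DataFrame(
        [
            {
                "protein_id": p.phospho.protein_id,
                "phospho_pos": p.phospho.native_pos,
                "ubiquitin_pos": p.ubiquitin.native_pos,
                "distance": p.distance,
            }
            for p in pairs
        ],
        columns=["protein_id", "phospho_pos", "ubiquitin_pos", "distance"],
    ).to_csv(crosstalk_path, sep="\t", index=False)
    outputs["crosstalk"] = crosstalk_path

    # projection
    if struct_chain is not None and mapping:
        projected = out / "projected.pdb"
        project_scores(structure_path, chain_a, mapping, scored, projected)
        outputs["projected"] = projected

    manifest = RunManifest(
        config=config.to_dict(),
        inputs=inputs,
        outputs=[str(p) for p in outputs.values()],
        version=__version__,
        seed=config.seed,
    )
    manifest.write(out / "manifest.json")
    outputs["manifest"] = out / "manifest.json"

    return PipelineResult(
        alignment=aln,
        maps=maps,
        scored=scored,
        outputs=outputs,
        enrichment=enrich_df,
        conservation=conservation,
    )
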