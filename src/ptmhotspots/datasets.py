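"""Packaged demonstration fixtures for the plant RGS (Regulator of
G-protein Signaling) case study.

The PTM site tables transcribe curated site lists for AtRGS1 and GmRGS2
(14 plant phosphosites) and the named functional sites of non-plant RGS
proteins. The sequences, alignments and coordinates are *synthetic*
stand-ins: deterministic generated sequences that carry the correct
residue at every annotated native position and emulate the conservation
structure of the real family, so the full pipeline can run end-to-end
without any external download. File names carry the ``synthetic_`` prefix
where the content stands in for a real reference object.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

_DATA = resources.files("ptmhotspots") / "data"


def _path(name: str) -> Path:
    return Path(str(_DATA / name))


def plant_alignment_path() -> Path:
    """Aligned FASTA of the plant 7TM-RGS sub-family (synthetic stand-in
    sequences for AtRGS1, GmRGS2 and six further plant members)."""
    return _path("synthetic_plant_rgs_alignment.fasta")


def plant_sites_path() -> Path:
    """The 14 plant phosphosites (8 on AtRGS1, 6 on GmRGS2)."""
    return _path("rgs_plant_sites.tsv")


def crosstalk_lysines_path() -> Path:
    """Candidate ubiquitination lysines near GmRGS2-S405 / AtRGS1-S406."""
    return _path("synthetic_rgs_crosstalk_lysines.tsv")


def family_alignment_path() -> Path:
    """Aligned FASTA of the PTM sub-family (synthetic stand-ins for
    non-plant RGS proteins harboring curated PTMs)."""
    return _path("synthetic_rgs_ptm_subfamily_alignment.fasta")


def family_sites_path() -> Path:
    """Curated functional PTM sites of the non-plant RGS members."""
    return _path("rgs_family_sites.tsv")


def regions_path() -> Path:
    """RGS-domain and cytoplasmic region annotations."""
    return _path("rgs_regions.tsv")


def structure_path() -> Path:
    """Synthetic two-chain coordinate set: AtRGS1 RGS-domain stand-in
    (chain A, residues 284-416) bound to a partner chain B, with a planted
    contact patch around AtRGS1-365 and AtRGS1-405/406."""
    return _path("synthetic_rgs_structure.pdb")


def rgs_demo() -> dict[str, Path]:
    """All fixture paths keyed by role."""
    return {
        "plant_alignment": plant_alignment_path(),
        "plant_sites": plant_sites_path(),
        "crosstalk_lysines": crosstalk_lysines_path(),
        "family_alignment": family_alignment_path(),
        "family_sites": family_sites_path(),
        "regions": regions_path(),
        "structure": structure_path(),
    }
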