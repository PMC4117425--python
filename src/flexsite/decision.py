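"""Druggability gates, site classification and the per-structure pipeline.

A site advances from the rigid structure when its reported Dscore+ exceeds
1.3; after flexibility modeling the bar rises to Dscore+ >= 1.7 together
with a drug-like volume of 160-800 A^3.  A *cryptic* druggable site is one
that is too small in the crystal structure (<= 100 A^3, not fully buried:
enclosure <= 96%) yet reaches the drug-like criteria once light flexibility
is modeled, on a chain of at least 100 residues.  Thresholds are applied to
scores rounded to one decimal, matching the reporting convention.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .descriptors import ScoreWeights, compute_descriptors, round_reported
from .flexibility import FlexConfig, flexible_result, induced_fit_cycle
from .pocket_finder import find_sites
from .site_grid import DetectionConfig, detect_fields, atom_vdw_radii
from .structure_io import KeepList, prepare, read_structure

__all__ = [
    "DecisionConfig",
    "DruggabilityRecord",
    "rigid_gate",
    "classify",
    "annotate_interfaces",
    "run_pipeline",
    "run_batch",
]


@dataclass(frozen=True)
class DecisionConfig:
    """Decision thresholds (defaults follow the published criteria)."""

    rigid_gate: float = 1.3            # advance when Dscore+ > this
    flexible_gate: float = 1.7         # druggable when flexible Dscore+ >= this
    druglike_volume: tuple = (160.0, 800.0)  # A^3, inclusive
    cryptic_max_initial_volume: float = 100.0  # A^3
    cryptic_max_enclosure: float = 96.0        # percent
    cryptic_strict_enclosure: bool = False     # True: strict '<' comparison
    min_protein_residues: int = 100
    interface_contact_distance: float = 2.0    # A, hydrogens included
    ligand_mw_max: float = 1000.0
    timeout: float = 3600.0            # s, per structure


@dataclass
class DruggabilityRecord:
    """Per-pocket decision object."""

    structure_id: str
    site_id: int
    rank: int
    rigid_dscore_plus: float
    rigid_volume: float
    rigid_enclosure_percent: float
    flexible_dscore_plus: float | None = None
    flexible_volume: float | None = None
    label: str = "not_advanced"
    rigid_druggable: bool = False
    ppi_interface: bool = False
    ligand_pocket: bool = False
    ligand_overlap_volume: float = 0.0
    chain_residues: int = 0
    notes: str = ""

    def to_json(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "site_id": int(self.site_id),
            "rank": int(self.rank),
            "rigid": {
                "dscore_plus": self.rigid_dscore_plus,
                "volume": round(self.rigid_volume, 1),
                "enclosure_percent": round(self.rigid_enclosure_percent, 1),
            },
            "flexible": None
            if self.flexible_dscore_plus is None
            else {
                "dscore_plus": self.flexible_dscore_plus,
                "volume": round(self.flexible_volume, 1),
            },
            "label": self.label,
            "rigid_druggable": self.rigid_druggable,
            "ppi_interface": self.ppi_interface,
            "ligand_pocket": self.ligand_pocket,
            "ligand_overlap_volume": round(self.ligand_overlap_volume, 1),
            "chain_residues": int(self.chain_residues),
            "notes": self.notes,
        }


def rigid_gate(dscore_plus_reported: float,
               cfg: DecisionConfig | None = None) -> bool:
    """Advance a site to flexibility modeling (strict > on the reported,
    one-decimal score)."""
    cfg = cfg or DecisionConfig()
    return dscore_plus_reported > cfg.rigid_gate


def _in_volume_range(v: float, cfg: DecisionConfig) -> bool:
    lo, hi = cfg.druglike_volume
    return lo <= v <= hi


def classify(record: DruggabilityRecord,
             cfg: DecisionConfig | None = None) -> DruggabilityRecord:
    """Assign the record's label from its rigid/flexible values.

    Raises on inconsistent inputs (flexible values without rigid values).
    """
    cfg = cfg or DecisionConfig()
    if record.flexible_dscore_plus is not None and np.isnan(record.rigid_dscore_plus):
        raise ValueError("flexible values present without rigid values")

    rigid_ok = rigid_gate(record.rigid_dscore_plus, cfg)
    record.rigid_druggable = bool(
        rigid_ok and _in_volume_range(record.rigid_volume, cfg)
    )

    if record.rigid_volume > cfg.druglike_volume[1]:
        record.label = "oversized_site"
        return record
    if not rigid_ok:
        record.label = "not_advanced"
        return record

    flex_ok = (
        record.flexible_dscore_plus is not None
        and record.flexible_dscore_plus >= cfg.flexible_gate
        and _in_volume_range(record.flexible_volume, cfg)
    )
    if flex_ok:
        if cfg.cryptic_strict_enclosure:
            enc_ok = record.rigid_enclosure_percent < cfg.cryptic_max_enclosure
        else:
            enc_ok = record.rigid_enclosure_percent <= cfg.cryptic_max_enclosure
        cryptic = (
            record.rigid_volume <= cfg.cryptic_max_initial_volume
            and enc_ok
            and record.chain_residues >= cfg.min_protein_residues
        )
        record.label = "cryptic_druggable" if cryptic else "druggable_flexible"
        return record
    if record.flexible_dscore_plus is None and record.rigid_druggable:
        record.label = "druggable_rigid"
        return record
    record.label = "difficult"
    return record


def annotate_interfaces(record: DruggabilityRecord, s, models: list,
                        site=None, grid=None,
                        cfg: DecisionConfig | None = None) -> DruggabilityRecord:
    """Flag protein-protein interface pockets (any TSN pose atom within the
    contact distance of another protein chain, hydrogens included) and
    ligand pockets (site cells overlapping a removed ligand's vdW
    envelope)."""
    cfg = cfg or DecisionConfig()

    # own chain = chain of the nearest protein heavy atom to the site centroid
    prot = (~s.is_het) & s.heavy_mask
    if site is not None and prot.any():
        d = np.linalg.norm(s.coords[prot] - site.centroid, axis=1)
        own_chain = str(s.chain_id[prot][np.argmin(d)])
        record.chain_residues = s.n_residues_per_chain().get(own_chain, 0)
    else:
        own_chain = None

    if models and own_chain is not None:
        other = (~s.is_het) & (s.chain_id != own_chain)
        if other.any():
            tree = cKDTree(s.coords[other])  # hydrogens included
            for m in models:
                if m.pose.probe != "TSN":
                    continue
                hits = tree.query_ball_point(
                    m.pose.coords, cfg.interface_contact_distance,
                    return_length=True,
                )
                if np.any(hits > 0):
                    record.ppi_interface = True
                    break

    removed = getattr(s, "removed_ligands", None)
    if site is not None and removed:
        h = grid.spacing if grid is not None else 0.35
        overlap_cells = 0
        for lig in removed:
            heavy = lig.elements != "H"
            radii = atom_vdw_radii(lig.elements[heavy])
            tree = cKDTree(lig.coords[heavy])
            d, j = tree.query(site.points, k=1)
            overlap_cells += int(np.sum(d <= radii[j]))
        record.ligand_overlap_volume = overlap_cells * h**3
        record.ligand_pocket = overlap_cells > 0
    return record


def run_pipeline(path, monomer: str | None = None,
                 det_cfg: DetectionConfig | None = None,
                 flex_cfg: FlexConfig | None = None,
                 dec_cfg: DecisionConfig | None = None,
                 weights: ScoreWeights | None = None,
                 keep_list: KeepList | None = None,
                 structure=None) -> list:
    """Full per-structure pipeline.

    prepare -> detect top sites -> rigid scores -> induced fit on gated
    sites -> classify -> annotate.  Emits one record per detected site.
    ``structure`` may supply an already-prepared structure (bypassing file
    I/O, e.g. for generated fixtures).
    """
    det_cfg = det_cfg or DetectionConfig()
    flex_cfg = flex_cfg or FlexConfig()
    dec_cfg = dec_cfg or DecisionConfig()
    weights = weights or ScoreWeights()
    t0 = time.monotonic()
    sid = str(path)

    if structure is None:
        raw = read_structure(path, "as-deposited" if monomer is None else monomer)
        s = prepare(raw, keep_list)
    else:
        s = structure

    grid = detect_fields(s, det_cfg)
    sites = find_sites(grid, det_cfg)
    records = []
    for site in sites:
        if time.monotonic() - t0 > dec_cfg.timeout:
            records.append(
                DruggabilityRecord(
                    structure_id=sid, site_id=site.site_id, rank=site.rank,
                    rigid_dscore_plus=float("nan"), rigid_volume=site.volume,
                    rigid_enclosure_percent=float("nan"),
                    notes="timeout before scoring",
                )
            )
            continue
        d = compute_descriptors(site, grid, det_cfg, weights)
        record = DruggabilityRecord(
            structure_id=sid,
            site_id=site.site_id,
            rank=site.rank,
            rigid_dscore_plus=d.reported_dscore_plus,
            rigid_volume=site.volume,
            rigid_enclosure_percent=d.e_percent,
        )
        models = []
        if rigid_gate(record.rigid_dscore_plus, dec_cfg) and not site.oversized:
            models = induced_fit_cycle(s, site, flex_cfg, det_cfg, weights)
            if models:
                try:
                    fdp, fv = flexible_result(models)
                    record.flexible_dscore_plus = fdp
                    record.flexible_volume = fv
                except ValueError:
                    pass
        annotate_interfaces(record, s, models, site=site, grid=grid, cfg=dec_cfg)
        classify(record, dec_cfg)
        records.append(record)
    return records


def run_batch(paths, **kwargs) -> list:
    """Records for a list of structures (processing order has no effect on
    any individual structure's records)."""
    out = []
    for p in sorted(str(x) for x in paths):
        try:
            out.extend(run_pipeline(p, **kwargs))
        except Exception as exc:  # propagate context, keep the batch going
            out.append(
                DruggabilityRecord(
                    structure_id=str(p), site_id=0, rank=0,
                    rigid_dscore_plus=float("nan"), rigid_volume=0.0,
                    rigid_enclosure_percent=float("nan"),
                    notes=f"error: {type(exc).__name__}: {exc}",
                )
            )
    return out


def records_to_json(records: list, path=None):
    payload = [r.to_json() for r in records]
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return payload
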