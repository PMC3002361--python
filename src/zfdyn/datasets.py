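"""Packaged reference tables for the seven Zif268-variant/DNA complexes.

The tables ship the published experimental dissociation constants and the
published per-complex descriptors (essential-subspace RMSF flexibility sums
and rank-1 stabilization-energy partitions) for the Zif268 zinc-finger
complexes 1A1F, 1A1G, 1A1I, 1A1J, 1A1K, 1A1L and 1AAY.  They let the
correlation stage run without the original trajectories.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .affinity import AffinityRecord


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("zfdyn.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def zif268_affinity() -> pd.DataFrame:
    """Complex id, recognition-helix motif, bound DNA quadruplet, Kd in nM."""
    return _load("zif268_affinity.tsv")


def zif268_flexibility() -> pd.DataFrame:
    """Per-complex RMSF sums (nm): protein-only and whole-complex."""
    return _load("zif268_flexibility.tsv")


def zif268_energetics() -> pd.DataFrame:
    """Per-complex stabilization-energy partition and intra-protein energy (kcal/mol)."""
    return _load("zif268_energetics.tsv")


def zif268_records() -> list[AffinityRecord]:
    """All packaged descriptors joined into affinity records, one per complex."""
    aff = zif268_affinity().set_index("complex_id")
    flex = zif268_flexibility().set_index("complex_id")
    ener = zif268_energetics().set_index("complex_id")
    records = []
    for cid, row in aff.iterrows():
        descriptors = {
            "protein_flexibility": float(flex.loc[cid, "protein_rmsf_sum_nm"]),
            "complex_flexibility": float(flex.loc[cid, "complex_rmsf_sum_nm"]),
            "protein_protein_energy": float(ener.loc[cid, "protein_protein_kcal"]),
            "protein_dna_energy": float(ener.loc[cid, "protein_dna_kcal"]),
            "dna_dna_energy": float(ener.loc[cid, "dna_dna_kcal"]),
            "total_stabilization_energy": float(ener.loc[cid, "total_kcal"]),
            "intraprotein_energy": float(ener.loc[cid, "intra_protein_kcal"]),
        }
        records.append(
            AffinityRecord(
                complex_id=str(cid), kd_nm=float(row["kd_nM"]), descriptors=descriptors
            )
        )
    return records
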