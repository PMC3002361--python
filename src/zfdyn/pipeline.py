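"""End-to-end orchestration: ensembles → descriptors → affinity correlations.

A declarative YAML/dict configuration lists one entry per complex (ensemble
files, a synthetic specification, or precomputed descriptors, plus its Kd)
and the analysis settings.  ``run_pipeline`` runs every stage per complex —
superposition, covariance/essential dynamics, RMSF flexibility sums,
Schlitter entropy, ICRM and rigidity profile, energy matrix and its
decomposition — then correlates every descriptor with log10(Kd) across
complexes and writes a machine-readable report with a reproducibility
manifest.

A failure in one complex is logged and isolated; the correlation stage
requires at least three surviving complexes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .affinity import AffinityRecord, correlate_descriptor, descriptor_table
from .dynamics import (
    covariance_matrix,
    essential_subspace,
    flexibility_sum,
    schlitter_entropy,
    subspace_rmsf,
)
from .energy import (
    EnergyMatrix,
    EnergyModelParams,
    decompose,
    hot_spots,
    intraprotein_energy,
    pair_energy_matrix,
    partition_stabilization,
    read_pair_energy_table,
)
from .ensemble import (
    CoordinateEnsemble,
    MoleculeClass,
    SiteTopology,
    concatenate_runs,
    nucleic_sites,
    protein_sites,
    read_multimodel_pdb,
    superpose,
)
from .icrm import (
    coordination_summary,
    icrm_matrix,
    rigidity_profile,
    write_icrm,
    write_rigidity_profile,
)
from .synthetic import (
    CovarianceSpec,
    PlantedEnergySpec,
    gaussian_ensemble,
    planted_energy_matrix,
)

log = logging.getLogger("zfdyn.pipeline")

#: Average site masses (amu) used when the topology carries none:
#: a mean amino-acid residue and a mean DNA nucleotide.
DEFAULT_PROTEIN_MASS = 110.0
DEFAULT_NUCLEIC_MASS = 308.0

DEFAULT_SETTINGS: dict[str, Any] = {
    "variance_fraction": 0.9,
    "trim_fraction": 0.25,
    "icrm_cap": 1.0e6,
    "stride": 1,
    "temperature_K": 300.0,
    "seed": 0,
    "dielectric_mode": "distance",
    "epsilon0": 4.0,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    complexes: list[dict[str, Any]]
    settings: dict[str, Any] = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_SETTINGS)
        merged.update(self.settings)
        self.settings = merged
        vf = self.settings["variance_fraction"]
        if not 0.0 < vf <= 1.0:
            raise ValueError("variance_fraction must be in (0, 1]")
        if self.settings["stride"] < 1:
            raise ValueError("stride must be >= 1")
        if not self.complexes:
            raise ValueError("config lists no complexes")
        for entry in self.complexes:
            if "id" not in entry or "kd_nM" not in entry:
                raise ValueError("every complex needs an id and a kd_nM")
            sources = [k for k in ("ensembles", "synthetic", "descriptors") if k in entry]
            if not sources:
                raise ValueError(
                    f"complex {entry['id']}: needs ensembles, synthetic or descriptors"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            complexes=raw.get("complexes", []),
            settings=raw.get("settings", {}),
            output_dir=raw.get("output_dir"),
        )


def _synthetic_complex(
    spec: Mapping[str, Any], seed: int
) -> tuple[list[SiteTopology], CoordinateEnsemble, EnergyMatrix]:
    """Build topology, ensemble and energy matrix from a synthetic spec."""
    n_protein = int(spec.get("n_protein", 25))
    n_dna = int(spec.get("n_dna", 8))
    n_frames = int(spec.get("n_frames", 300))
    scale = float(spec.get("flexibility_scale", 1.0))
    n = n_protein + n_dna
    topology = [
        SiteTopology(
            site_index=i,
            chain_id="A" if i < n_protein else "B",
            residue_number=i + 1,
            residue_name="ALA" if i < n_protein else "DA",
            molecule_class=(
                MoleculeClass.PROTEIN if i < n_protein else MoleculeClass.NUCLEIC
            ),
            representative_atom="CA" if i < n_protein else "C1'",
        )
        for i in range(n)
    ]
    rng = np.random.default_rng(seed)
    # self-avoiding-ish random walk with ~0.38 nm steps as a mean structure
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    mean = np.cumsum(0.38 * steps, axis=0)
    cov = CovarianceSpec(
        elastic_network=(
            float(spec.get("cutoff_nm", 1.0)),
            float(spec.get("spring_constant", 100.0)) / scale,
            float(spec.get("temperature_K", 300.0)),
        )
    )
    ensemble = gaussian_ensemble(mean, cov, n_frames, seed=seed + 1)
    planted = PlantedEnergySpec(
        n_sites=n,
        hotspot_indices=frozenset(spec.get("hotspots", [0, 1])),
        hotspot_weight_ratio=float(spec.get("hotspot_weight_ratio", 3.0)),
        leading_eigenvalue=float(spec.get("leading_eigenvalue", -1000.0)),
        noise_sd=float(spec.get("noise_sd", 0.0)),
        seed=seed + 2,
    )
    return topology, ensemble, planted_energy_matrix(planted)


def _analyse_complex(
    entry: Mapping[str, Any], settings: Mapping[str, Any], out_dir: Path | None
) -> AffinityRecord:
    cid = str(entry["id"])
    if "descriptors" in entry:
        return AffinityRecord(
            complex_id=cid,
            kd_nm=float(entry["kd_nM"]),
            descriptors={k: float(v) for k, v in entry["descriptors"].items()},
        )

    energy_matrix: EnergyMatrix | None = None
    if "ensembles" in entry:
        runs = []
        topology = None
        for path in entry["ensembles"]:
            topo, ens = read_multimodel_pdb(path)
            topology = topology or topo
            runs.append(ens)
        ensemble = concatenate_runs(runs, trim_fraction=settings["trim_fraction"])
    else:
        cid_digest = int.from_bytes(
            hashlib.sha256(cid.encode()).digest()[:2], "big"
        )
        topology, ensemble, energy_matrix = _synthetic_complex(
            entry["synthetic"], seed=(int(settings["seed"]) * 65536 + cid_digest) % (2**31 - 1)
        )
    if "energy_table" in entry:
        energy_matrix = read_pair_energy_table(entry["energy_table"])

    fitted = ensemble if ensemble.superposed else superpose(ensemble)
    model = covariance_matrix(fitted)
    m = essential_subspace(model, settings["variance_fraction"])
    profile = subspace_rmsf(fitted, model, m)
    P = protein_sites(topology)
    D = nucleic_sites(topology)
    masses = np.array(
        [
            s.mass
            if s.mass is not None
            else (
                DEFAULT_PROTEIN_MASS
                if s.molecule_class == MoleculeClass.PROTEIN
                else DEFAULT_NUCLEIC_MASS
            )
            for s in topology
        ]
    )
    entropy = schlitter_entropy(model, masses, settings["temperature_K"])
    icrm = icrm_matrix(fitted, cap_value=settings["icrm_cap"])
    rigidity = rigidity_profile(icrm)

    descriptors = {
        "protein_flexibility": flexibility_sum(profile, P),
        "complex_flexibility": flexibility_sum(profile),
        "entropy": entropy.value,
        "coordination": coordination_summary(icrm),
        "essential_dim": float(m),
    }
    if energy_matrix is None:
        model_params = EnergyModelParams(
            dielectric_mode=settings["dielectric_mode"],
            epsilon0=settings["epsilon0"],
        )
        try:
            energy_matrix = pair_energy_matrix(
                ensemble, topology, model_params, stride=int(settings["stride"])
            )
        except ValueError:
            log.warning("%s: no charges available, skipping energy stages", cid)
    if energy_matrix is not None:
        result = decompose(energy_matrix)
        partition = partition_stabilization(result, topology)
        hotspots = hot_spots(result)
        descriptors.update(
            {
                "total_stabilization_energy": result.approx_energy,
                "protein_protein_energy": partition.protein_protein,
                "protein_dna_energy": partition.protein_dna,
                "dna_dna_energy": partition.dna_dna,
                "n_hot_spots": float(len(hotspots.indices)),
            }
        )
        if len(P) >= 2:
            descriptors["intraprotein_energy"] = intraprotein_energy(
                energy_matrix, topology
            )

    if out_dir is not None:
        cdir = out_dir / cid
        cdir.mkdir(parents=True, exist_ok=True)
        labels = [s.label for s in topology]
        import pandas as pd

        pd.DataFrame({"site": labels, "rmsf_nm": profile.rmsf}).to_csv(
            cdir / "rmsf.tsv", sep="\t", index=False
        )
        pd.DataFrame({"eigenvalue_nm2": model.eigenvalues}).to_csv(
            cdir / "spectrum.tsv", sep="\t", index=False
        )
        write_icrm(cdir / "icrm.tsv", icrm, labels)
        write_rigidity_profile(cdir / "rigidity.tsv", rigidity, labels)
    return AffinityRecord(
        complex_id=cid, kd_nm=float(entry["kd_nM"]), descriptors=descriptors
    )


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Run every stage for every complex and the cross-complex correlations.

    Returns the report dict; when ``out_dir`` (or ``config.output_dir``) is
    set, writes ``report.json``, ``manifest.json`` and per-complex artifact
    files there.  The report content is a pure function of the configuration,
    including its seed.
    """
    out = Path(out_dir or config.output_dir) if (out_dir or config.output_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    records: list[AffinityRecord] = []
    failures: dict[str, str] = {}
    for entry in config.complexes:
        cid = str(entry["id"])
        try:
            records.append(_analyse_complex(entry, config.settings, out))
            log.info("complex %s: analysed", cid)
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            log.error("complex %s failed: %s", cid, exc)
            failures[cid] = str(exc)

    report: dict[str, Any] = {
        "complexes": {
            rec.complex_id: {"kd_nM": rec.kd_nm, **rec.descriptors}
            for rec in records
        },
        "failures": failures,
        "correlations": {},
    }
    if len(records) >= 3:
        names = sorted(set.intersection(*(set(r.descriptors) for r in records)))
        for name in names:
            try:
                c = correlate_descriptor(records, name)
            except ValueError:
                continue
            report["correlations"][name] = {
                "r": round(c.r, 10),
                "n": c.n,
                "slope": round(c.slope, 10),
                "intercept": round(c.intercept, 10),
            }
    elif config.complexes:
        report["correlations_error"] = (
            "fewer than 3 complexes analysed successfully; correlations skipped"
        )

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        manifest = {
            "zfdyn_version": __version__,
            "settings": config.settings,
            "config_digest": hashlib.sha256(
                json.dumps(
                    {"complexes": config.complexes, "settings": config.settings},
                    sort_keys=True,
                    default=str,
                ).encode()
            ).hexdigest(),
            "n_complexes": len(config.complexes),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        if records:
            descriptor_table(records).to_csv(
                out / "descriptors.tsv", sep="\t", index=False
            )
    return report
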