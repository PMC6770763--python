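"""Synthetic test-data generators.

Three generators cover the three kinds of input the pipeline consumes:

* :func:`generate_cascade_network` — a layered receptor → kinase-cascade →
  transcription network with known kinetic parameters, shaped like the
  neuroblastoma signaling network it stands in for: EGF/NGF ligand inputs,
  an ALK node and an EGFR node feeding parallel kinase chains that converge
  on transcription of a PD-L1 mRNA readout;
* :func:`generate_observations` — noisy time-course observations of a
  simulated model, fuel for parameter-recovery tests of the fitting stage;
* :func:`generate_expression_matrix` — a log2-scale probe×sample microarray
  matrix over a 2D/3D culture × DMSO/crizotinib/alectinib design with
  planted per-condition effects, emulating the validation dataset.

Every generator is a pure function of its spec plus seed.  The kinetics
noise model is multiplicative Gaussian on the relative scale; the array
noise model is additive Gaussian on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import Compartment, KineticLaw, NetworkModel, Reaction, Species
from .ode import SimulationSettings, Trajectory, simulate

__all__ = [
    "CascadeSpec",
    "GeneratedNetwork",
    "generate_cascade_network",
    "reference_cascade",
    "REFERENCE_SPEC",
    "REFERENCE_SETTINGS",
    "generate_observations",
    "generate_expression_matrix",
    "CULTURES",
    "TREATMENTS",
]

#: Canonical species ids the scenario machinery targets.
SINK_ID = "sink"
GENE_ID = "PDL1_gene"
MRNA_ID = "PDL1_mRNA"

CULTURES = ("2D", "3D")
TREATMENTS = ("DMSO", "crizotinib", "alectinib")


@dataclass(frozen=True)
class CascadeSpec:
    """Topology and parameter ranges for a generated cascade.

    Rate constants are drawn uniformly from the stated ranges with the given
    seed.  ``egfr_drive_scale`` down-weights the EGFR branch's transcription
    drive relative to the ALK branch so the readout is ALK-dominated, the
    regime in which EGFR inhibition leaves PD-L1 essentially unchanged.
    Ligands decay slowly (first order), so ligand-driven signaling is
    transient while a constitutively active mutant keeps driving
    transcription — hence a wild-type plateau versus near-linear mutant
    growth of the readout.
    """

    n_layers: int = 3
    species_per_layer: int = 1
    include_alk_branch: bool = True
    include_egfr_branch: bool = True
    egfr_drive_scale: float = 1e-3
    kcat_range: tuple[float, float] = (0.1, 0.3)
    km_range: tuple[float, float] = (0.3, 1.0)
    deactivation_k_range: tuple[float, float] = (0.5, 1.0)
    ligand_dose: float = 0.5  # mmol/mL, EGF and NGF stimulation level
    ligand_decay_k: float = 0.1  # 1/s
    receptor_init: float = 1.0  # mmol/mL inactive receptor / kinase pools
    transcription_kcat: float = 0.05
    transcription_km: float = 0.5
    gene_init: float = 1.0
    mrna_decay_k: float = 1e-4  # slow: readout accumulates over the run
    seed: int = 0


class GeneratedNetwork(NamedTuple):
    model: NetworkModel
    parameters: dict[tuple[str, str], float]  # (reaction id, parameter) -> truth


def _activation_pair(
    model: NetworkModel, inactive_id: str, active_id: str, name: str, init: float
) -> None:
    model.add_species(
        Species(
            id=inactive_id,
            name=name,
            role="protein",
            activation_state="inactive",
            initial_concentration=init,
            counterpart=active_id,
        )
    )
    model.add_species(
        Species(
            id=active_id,
            name=f"{name} (active)",
            role="protein",
            activation_state="active",
            initial_concentration=0.0,
            counterpart=inactive_id,
        )
    )


def generate_cascade_network(spec: CascadeSpec) -> GeneratedNetwork:
    """Build a layered signaling cascade with known ground-truth parameters.

    Structure per included branch (ALK driven by NGF, EGFR driven by EGF):
    ligand-modified receptor activation, ``n_layers`` of kinase
    activation/deactivation pairs, and a terminal transcription reaction in
    which the last active kinase drives production of the PD-L1 mRNA
    readout.  Returns the model together with a ``(reaction id, parameter)
    → value`` record of every drawn constant.
    """
    if spec.n_layers < 2:
        raise ValueError("cascade needs at least 2 layers")
    if spec.species_per_layer < 1:
        raise ValueError("species_per_layer must be >= 1")
    rng = np.random.default_rng(spec.seed)
    truth: dict[tuple[str, str], float] = {}

    model = NetworkModel(metadata={"generator": "cascade", "seed": str(spec.seed)})
    model.add_compartment(
        Compartment(id="cytoplasm", name="Neuroblastoma Cell Cytoplasm", volume=1.0)
    )
    model.add_species(Species(id=SINK_ID, name="degraded", role="sink"))
    model.add_species(
        Species(id=GENE_ID, name="PD-L1 gene", role="gene",
                initial_concentration=spec.gene_init)
    )
    model.add_species(Species(id=MRNA_ID, name="PD-L1 mRNA", role="mRNA"))
    model.output_species = MRNA_ID

    def draw(lo_hi: tuple[float, float]) -> float:
        return float(rng.uniform(*lo_hi))

    def add_interconversion(
        rid: str, inactive: str, active: str, driver: str
    ) -> None:
        kcat, km = draw(spec.kcat_range), draw(spec.km_range)
        model.add_reaction(
            Reaction(
                id=rid,
                substrates=[(inactive, 1)],
                products=[(active, 1)],
                modifiers=[driver],
                law=KineticLaw.modified_hmm(kcat, km, driver),
                category="activation/inhibition",
            )
        )
        truth[(rid, "Kcat")] = kcat
        truth[(rid, "Km")] = km
        k_off = draw(spec.deactivation_k_range)
        model.add_reaction(
            Reaction(
                id=f"{rid}_off",
                substrates=[(active, 1)],
                products=[(inactive, 1)],
                law=KineticLaw.mass_action(k_off),
                category="activation/inhibition",
            )
        )
        truth[(f"{rid}_off", "k1")] = k_off

    branches: list[tuple[str, str, str, str]] = []  # tag, ligand, inactive, active
    if spec.include_alk_branch:
        branches.append(("ALK", "NGF", "ALK", "ALK_active"))
    if spec.include_egfr_branch:
        branches.append(("EGFR", "EGF", "EGFR_free", "EGFR_active"))
    if not branches:
        raise ValueError("at least one receptor branch must be included")

    for tag, ligand, r_inactive, r_active in branches:
        model.add_species(
            Species(
                id=ligand,
                name=ligand,
                role="simple molecule",
                initial_concentration=spec.ligand_dose,
            )
        )
        _activation_pair(model, r_inactive, r_active, tag, spec.receptor_init)
        add_interconversion(f"{tag}_activation", r_inactive, r_active, ligand)

        upstream = [r_active]
        for layer in range(1, spec.n_layers + 1):
            current = []
            for j in range(spec.species_per_layer):
                base = f"{tag}_K{layer}" + (f"_{j}" if spec.species_per_layer > 1 else "")
                _activation_pair(
                    model, base, f"{base}_active", base, spec.receptor_init
                )
                for u, drv in enumerate(upstream):
                    suffix = f"_via{u}" if len(upstream) > 1 else ""
                    add_interconversion(
                        f"{base}_activation{suffix}", base, f"{base}_active", drv
                    )
                current.append(f"{base}_active")
            upstream = current

        drive = spec.transcription_kcat * (
            spec.egfr_drive_scale if tag == "EGFR" else 1.0
        )
        rid = f"{tag}_transcription"
        for u, terminal in enumerate(upstream):
            r = rid + (f"_via{u}" if len(upstream) > 1 else "")
            model.add_reaction(
                Reaction(
                    id=r,
                    substrates=[(GENE_ID, 1)],
                    products=[(GENE_ID, 1), (MRNA_ID, 1)],
                    modifiers=[terminal],
                    law=KineticLaw.modified_hmm(
                        drive, spec.transcription_km, terminal
                    ),
                    category="transcription",
                )
            )
            truth[(r, "Kcat")] = drive
            truth[(r, "Km")] = spec.transcription_km

        model.add_reaction(
            Reaction(
                id=f"{ligand}_degradation",
                substrates=[(ligand, 1)],
                products=[(SINK_ID, 1)],
                law=KineticLaw.mass_action(spec.ligand_decay_k),
                category="degradation",
            )
        )
        truth[(f"{ligand}_degradation", "k1")] = spec.ligand_decay_k

    model.add_reaction(
        Reaction(
            id="PDL1_mRNA_degradation",
            substrates=[(MRNA_ID, 1)],
            products=[(SINK_ID, 1)],
            law=KineticLaw.mass_action(spec.mrna_decay_k),
            category="degradation",
        )
    )
    truth[("PDL1_mRNA_degradation", "k1")] = spec.mrna_decay_k
    return GeneratedNetwork(model, truth)


#: The frozen reference cascade used by scenario-direction tests: the fixed
#: spec (defaults above) and seed stand in for the full curated network in
#: every qualitative comparison.
REFERENCE_SPEC = CascadeSpec(seed=2019)

#: Companion time-course settings for the reference cascade: long enough for
#: ligand-driven (wild-type) signaling to decay and plateau while a
#: constitutive mutant keeps accumulating readout.
REFERENCE_SETTINGS = SimulationSettings(
    duration=100.0, n_intervals=200, relative_tolerance=1e-8,
    absolute_tolerance=1e-12,
)


def reference_cascade() -> GeneratedNetwork:
    """The fixed, documented cascade used throughout the test fleet."""
    return generate_cascade_network(REFERENCE_SPEC)


def generate_observations(
    model: NetworkModel,
    settings: SimulationSettings,
    observed_species: Sequence[str],
    noise_sd_rel: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    trajectory: Trajectory | None = None,
) -> pd.DataFrame:
    """Simulate and emit noisy observations as a tidy table.

    Columns: ``species``, ``time``, ``value``, ``weight``, ``replicate``.
    Noise is multiplicative Gaussian: ``value = truth · (1 + ε)`` with
    ``ε ~ N(0, noise_sd_rel)``; ``noise_sd_rel = 0`` returns the simulated
    values exactly.  Pass a precomputed ``trajectory`` to skip re-simulation.
    """
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be >= 0")
    traj = trajectory if trajectory is not None else simulate(model, settings)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        for sid in observed_species:
            truth = traj.concentration(sid)
            noise = rng.normal(0.0, noise_sd_rel, size=truth.shape) if noise_sd_rel else 0.0
            values = truth * (1.0 + noise)
            for t, v in zip(traj.times, values):
                rows.append((sid, float(t), float(v), 1.0, rep))
    return pd.DataFrame(
        rows, columns=["species", "time", "value", "weight", "replicate"]
    )


def generate_expression_matrix(
    n_probes: int = 200,
    n_per_cell: int = 3,
    planted_log2_effects: dict[tuple[str, str, str], float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    pdl1_probe: str = "probe_PDL1",
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> ExpressionMatrix:
    """Log2-scale probe×sample matrix over the 2D/3D × DMSO/criz/alectinib design.

    Each probe gets a baseline drawn from N(``baseline_mean``,
    ``baseline_sd``) shared across samples; ``planted_log2_effects`` maps
    ``(probe, culture, treatment)`` to a log2 shift added to that probe in
    the matching condition; additive N(0, ``noise_sd``) noise is applied per
    entry.  The PD-L1 probe id is included among the probes.
    """
    if n_probes < 1 or n_per_cell < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    effects = planted_log2_effects or {}

    probes = [pdl1_probe] + [f"probe_{i:04d}" for i in range(1, n_probes)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_probes)

    columns, annotations = [], []
    data = np.zeros((n_probes, len(CULTURES) * len(TREATMENTS) * n_per_cell))
    col = 0
    for culture in CULTURES:
        for treatment in TREATMENTS:
            for rep in range(1, n_per_cell + 1):
                sample = f"{culture}_{treatment}_{rep}"
                shift = np.array(
                    [effects.get((p, culture, treatment), 0.0) for p in probes]
                )
                noise = rng.normal(0.0, noise_sd, size=n_probes) if noise_sd else 0.0
                data[:, col] = baseline + shift + noise
                columns.append(sample)
                annotations.append((sample, culture, treatment))
                col += 1

    values = pd.DataFrame(data, index=probes, columns=columns)
    samples = pd.DataFrame(
        annotations, columns=["sample", "culture", "treatment"]
    ).set_index("sample")
    return ExpressionMatrix(values=values, samples=samples, scale="log2")
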