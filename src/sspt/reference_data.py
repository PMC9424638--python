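"""Published reference measurements used as inputs throughout the package.

These are the study's printed numbers for the adenine-riboswitch (riboA)
crystal system: replicate uncaging yields at three UV exposure times, the
UV beam/drop geometry and measured powers, and the best-fit kinetic
parameter columns for the three reference crystals (small S2, medium M3,
large L1) together with the transition times observed by PVM for their
1×1 µm ROIs.  They serve as fixed inputs for reproducing the derived
quantities (means, power densities, illuminated fraction, nominal
concentration, simulated inflection times); nothing here is fitted at
import time.
"""

from __future__ import annotations

from .kinetics import KineticParameters
from .photochemistry import BeamGeometry, UncagingReplicates

__all__ = [
    "UNCAGING_DIRECT",
    "UNCAGING_MICROSCOPE",
    "MICROSCOPE_BEAM",
    "DIRECT_BEAM",
    "PCADE_STOCK_MM",
    "RNA_CONC_MM",
    "CRYSTAL_FITS",
    "OBSERVED_T1_S",
]

#: Replicate % ADE released, LED applied directly (no microscope optics).
UNCAGING_DIRECT = {
    1: UncagingReplicates(1.0, "direct", (32.9, 34.5, 36.9)),
    5: UncagingReplicates(5.0, "direct", (61.0, 57.8, 66.9)),
    10: UncagingReplicates(10.0, "direct", (64.3, 60.4, 67.5)),
}

#: Replicate % ADE released with the LED focused through the microscope.
UNCAGING_MICROSCOPE = {
    1: UncagingReplicates(1.0, "microscope", (8.9, 8.1, 10.4)),
    5: UncagingReplicates(5.0, "microscope", (23.7, 28.1, 24.5)),
    10: UncagingReplicates(10.0, "microscope", (28.5, 30.0, 26.1)),
}

#: Microscope-integrated beam: 0.24 mm spot, 12.7 mW, 2.1 mm (1 µl) drop.
MICROSCOPE_BEAM = BeamGeometry(
    beam_diameter_mm=0.24, power_mW=12.7, drop_diameter_mm=2.1
)

#: Direct exposure measured through a 1 mm pinhole aperture: 120 mW.
DIRECT_BEAM = BeamGeometry(
    beam_diameter_mm=1.0, power_mW=120.0, aperture_diameter_mm=1.0
)

#: pcADE soaking concentration, mM.
PCADE_STOCK_MM = 10.0

#: In-crystal concentration of each apo conformer, mM.
RNA_CONC_MM = 16.0

#: Best-fit four-state parameters per crystal (B0 mM; rate constants as
#: printed, applied per the package's default convention).
CRYSTAL_FITS = {
    "S2": KineticParameters(B0_mM=0.46, k_op=2.35e-4, k_on=3.00e-2, k_f=0.5,
                            R0_mM=RNA_CONC_MM),
    "M3": KineticParameters(B0_mM=0.42, k_op=2.00e-4, k_on=3.00e-2, k_f=1.0,
                            R0_mM=RNA_CONC_MM),
    "L1": KineticParameters(B0_mM=0.43, k_op=1.60e-4, k_on=3.00e-2, k_f=0.9,
                            R0_mM=RNA_CONC_MM),
}

#: PVM-observed transition times (s) for the 1×1 µm ROIs of the same crystals.
OBSERVED_T1_S = {"S2": 55.7, "M3": 60.4, "L1": 72.1}
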