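"""Fixed physical constants and reference values used across the pipeline.

All diffusivities are stored internally in mm^2/s. Values quoted in the
micro-structure literature in um^2/ms are numerically equal to
10^-3 mm^2/s and are converted at the boundary.
"""

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

#: NODDI intrinsic stick (intra-neurite) diffusivity, mm^2/s.
NODDI_D_PAR = 1.7e-3

#: NODDI isotropic (free-water) diffusivity, mm^2/s.
NODDI_D_ISO = 3.0e-3

#: SANDI soma diffusivity (3 um^2/ms), mm^2/s.
SANDI_D_IS = 3.0e-3

#: Diffusivity assumed for the extracellular-water compartment, mm^2/s.
DECW = 3.0e-3

#: Default ratio of intracellular to extracellular ionic concentrations.
#: Not measurable from diffusion data; the CTI literature this pipeline
#: follows (Sajib et al.) uses 0.41. Exposed in every config and manifest.
BETA_DEFAULT = 0.41

#: Cap applied to the Watson concentration parameter kappa as ODI -> 0.
KAPPA_CAP = 1.0e6

#: Smallest admissible sigma_L denominator (alpha*de + beta*(1-alpha)*di),
#: mm^2/s, before a voxel is masked out.
DENOMINATOR_FLOOR = 1.0e-12

#: Default evaluation frequency for the high-frequency conductivity, Hz
#: (3 T proton Larmor frequency, conventionally quoted as 128 MHz).
FREQ_DEFAULT = 128.0e6

#: Reference high-frequency conductivities at 128 MHz, S/m, as assigned to
#: the three tissue classes in the modeled sigma_H atlas. These are the
#: fixed per-class defaults; the Cole-Cole dispersion model in
#: :mod:`ctisim.sigma_high` reproduces them to ~3e-4 S/m and is used for
#: any other frequency.
SIGMA_H_128MHZ = {"GM": 0.5864, "WM": 0.3420, "CSF": 2.1429}
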