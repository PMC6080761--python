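"""Physical constants and fixed conventions of the pipeline.

All energies are in kcal/mol, all lengths in Å, temperatures in K.
"""

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872041

#: Simulation temperature (K). The whole pipeline operates at 300 K.
TEMPERATURE = 300.0

#: k_B * T at the default temperature, kcal/mol.
KT = KB * TEMPERATURE

#: Reaction-coordinate domain over which surfaces are defined (Å).
DOMAIN = (-2.0, 2.0)

#: Soft-wall onset: quadratic confinement is added outside +/- this value (Å).
WALL_ONSET = 1.8

#: Stiffness of the confinement wall (kcal/mol/Å²).
WALL_K = 200.0

#: Umbrella-window force constant (kcal/mol/Å²).
DEFAULT_FORCE_CONSTANT = 150.0

#: Window ladder endpoints and spacing (Å).
WINDOW_MIN = -1.7
WINDOW_MAX = 1.7
WINDOW_STEP = 0.1

#: Monte-Carlo sweeps corresponding to 1 ps of the original molecular dynamics.
SWEEPS_PER_PS = 500
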