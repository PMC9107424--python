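"""Repository-wide numerical tolerances.

These constants are referenced by every module so that a tolerance is defined
exactly once.  Values are absolute unless noted otherwise.
"""

#: Maximum allowed asymmetry ``max|M - M.T|`` for matrices that must be symmetric.
SYMMETRY_TOL = 1e-8

#: Maximum allowed deviation of a correlation-matrix diagonal from 1.
DIAGONAL_TOL = 1e-6

#: Slack allowed on the [-1, 1] range of correlation entries.
ENTRY_SLACK = 1e-9

#: A correlation matrix may have eigenvalues down to -PSD_TOL (numerical noise).
PSD_TOL = 1e-8

#: Default ridge added to a correlation matrix to push it into the SPD cone.
DEFAULT_MU = 1e-10

#: Largest ridge tried by the adaptive escalation before giving up.
MAX_MU = 1e-4

#: Convergence tolerance of the eigenvector-centrality power iteration.
POWER_ITERATION_TOL = 1e-10

#: Iteration budget of the power iteration.
POWER_ITERATION_MAXITER = 1000
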