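"""Reference data for the 37-founder yeast deletion panel.

The panel below is the published founder set used throughout the package's
documentation and as the default design of the synthetic-data generator:
37 single-gene deletion strains of *S. cerevisiae* grouped into 16 functional
modules (defined by correlated genetic-interaction profiles) plus a neutral
negative control (*ho*) and a positive control for functionally dependent
adaptation (*ade2*).  ``initial_fitness`` is the competitive fitness of the
deletion founder relative to the wild-type ancestor, in percent per
generation; ``gain_mean``/``gain_sd`` are the mean and standard deviation of
the fitness gain of the 20 replicate populations evolved from each founder
for 500 generations.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_panel",
    "REFERENCE_FITNESS_MODELS",
    "REFERENCE_EPISTASIS_MODELS",
]

# (module, gene, initial fitness %/gen, mean gain %/gen, sd of gain %/gen)
_PANEL_ROWS = [
    ("Central metabolism 1", "hxk2", -24.5, 13.4, 2.9),
    ("Central metabolism 1", "tps1", -24.4, 21.8, 2.3),
    ("Central metabolism 2", "lat1", -13.9, 9.2, 2.4),
    ("Central metabolism 2", "pda1", 0.1, 3.3, 1.2),
    ("Central metabolism 2", "pdb1", -15.5, 9.7, 2.7),
    ("Electron transport chain", "coq2", -4.6, 4.3, 1.5),
    ("Electron transport chain", "cox14", -5.2, 4.5, 1.3),
    ("Electron transport chain", "cox6", -9.8, 6.5, 1.0),
    ("Elongator complex", "elp4", -14.0, 2.7, 1.1),
    ("Elongator complex", "elp6", -14.2, 2.6, 0.9),
    ("Elongator complex", "kti12", -12.2, 3.6, 1.3),
    ("Elongator complex", "ncs2", -13.1, 2.6, 0.4),
    ("Elongator complex", "uba4", -13.8, 3.3, 0.6),
    ("Golgi/endosome/vacuole 1", "get1", -7.3, 3.4, 1.4),
    ("Golgi/endosome/vacuole 1", "get2", -10.4, 9.1, 1.0),
    ("Golgi/endosome/vacuole 2", "pep8", -1.6, 3.6, 1.3),
    ("Golgi/endosome/vacuole 2", "vps29", -1.9, 3.3, 1.1),
    ("Golgi/endosome/vacuole 2", "vps35", -1.9, 2.4, 1.0),
    ("Kinetochore", "chl4", -0.5, 2.2, 0.6),
    ("Kinetochore", "ctf19", -1.1, 1.1, 0.8),
    ("Kinetochore", "iml3", -0.4, 2.5, 0.8),
    ("Morphogenesis", "arc18", 3.9, -0.0, 1.4),
    ("Morphogenesis", "she4", -20.4, 7.0, 3.1),
    ("Nuclear migration", "arp1", -3.0, 5.4, 0.5),
    ("Nuclear migration", "nip100", -8.7, 8.2, 1.4),
    ("Peripheral metabolism", "erg3", -6.3, 1.4, 1.4),
    ("Peripheral metabolism", "erg5", -1.7, 3.2, 2.2),
    ("Peripheral metabolism", "erg6", -6.8, 1.9, 1.7),
    ("RNA processing", "lsm1", -10.1, 2.0, 0.8),
    ("RNA processing", "pat1", -13.5, 4.6, 0.5),
    ("Ras signaling 1", "bmh1", -3.4, 6.4, 1.5),
    ("Ras signaling 2", "ira2", -4.4, 7.8, 1.0),
    ("Nuclear pore", "nup2", -2.3, 4.1, 0.7),
    ("Stress response 1", "sfl1", -1.3, 4.1, 0.9),
    ("Stress response 2", "sok2", -1.9, 4.8, 0.8),
    ("Negative control", "ho", -0.0, 3.4, 1.3),
    ("Positive control", "ade2", -23.0, 16.7, 1.5),
]


def reference_panel() -> pd.DataFrame:
    """Return the reference founder panel as a DataFrame.

    Columns: ``module``, ``gene``, ``initial_fitness`` (% per generation),
    ``gain_mean``, ``gain_sd`` (% per generation, over 20 replicate
    populations per founder).
    """
    return pd.DataFrame(
        _PANEL_ROWS,
        columns=["module", "gene", "initial_fitness", "gain_mean", "gain_sd"],
    )


# Published maximum-likelihood estimates of the nested hierarchical models of
# the 500-generation fitness gain, keyed by the fixed/random terms included.
# Units: alpha in %/gen, beta dimensionless, sigmas in %/gen, loglik in nats.
REFERENCE_FITNESS_MODELS = {
    "g+p": dict(alpha=4.96, beta=None, sigma_m=None, sigma_g=4.29,
                sigma_p=1.45, sigma_tau=0.81, loglik=-2833.0),
    "m+g+p": dict(alpha=5.40, beta=None, sigma_m=3.83, sigma_g=2.47,
                  sigma_p=1.45, sigma_tau=0.81, loglik=-2828.0),
    "b+g+p": dict(alpha=1.35, beta=-0.42, sigma_m=None, sigma_g=3.04,
                  sigma_p=1.45, sigma_tau=0.81, loglik=-2823.0),
    "b+m+g+p": dict(alpha=2.01, beta=-0.39, sigma_m=2.47, sigma_g=1.78,
                    sigma_p=1.45, sigma_tau=0.81, loglik=-2817.0),
}

# Same models fitted to per-population epistasis (deletion-background effect of
# the evolved mutations minus their wild-type-background effect).
REFERENCE_EPISTASIS_MODELS = {
    "g+p": dict(alpha=3.85, beta=None, sigma_m=None, sigma_g=7.23,
                sigma_p=2.66, sigma_tau=0.49, loglik=-479.0),
    "m+g+p": dict(alpha=4.89, beta=None, sigma_m=7.56, sigma_g=0.00,
                  sigma_p=2.71, sigma_tau=0.49, loglik=-463.0),
    "b+g+p": dict(alpha=-1.88, beta=-0.73, sigma_m=None, sigma_g=4.42,
                  sigma_p=2.65, sigma_tau=0.49, loglik=-465.0),
    "b+m+g+p": dict(alpha=0.44, beta=-0.58, sigma_m=4.39, sigma_g=0.00,
                    sigma_p=2.56, sigma_tau=0.49, loglik=-450.0),
}
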