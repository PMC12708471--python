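"""Independent continuous-time oracles used by the lifetable checks."""
import numpy as np

from mortlag.agegrid import CANONICAL


def gompertz_continuous_e0(a, b, c, dx=0.01, max_age=130.0):
    """Survival integration of a Gompertz-Makeham hazard on a fine age grid."""
    x = np.arange(0, max_age + dx, dx)
    h = a * np.exp(b * x) + c
    H = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2.0 * dx)])
    l = np.exp(-H)
    return np.trapezoid(l, x), x, h, l


def gompertz_group_rates(a, b, c):
    """Occurrence/exposure rates per canonical group from the continuous model."""
    _, x, h, l = gompertz_continuous_e0(a, b, c)
    m = []
    bounds = list(CANONICAL.starts) + [x[-1]]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (x >= lo) & (x < hi)
        exposure = np.trapezoid(l[sel], x[sel])
        deaths = np.trapezoid((h * l)[sel], x[sel])
        m.append(deaths / exposure)
    return np.array(m)
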