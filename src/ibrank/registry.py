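"""Strategy registry binding method tags to estimator classes.

Every tag satisfies the common contract: ``fit`` consumes only the
training matrix (plus construction-time config), ``rank`` consumes the
informer assay data.
"""

from __future__ import annotations

from typing import Callable

from .adaptive import AdaptiveSelector
from .base import InformerStrategy
from .baselines import ChemometricBaseline, FrequentHitterBaseline
from .coding import CodingSelector
from .regression import RegressionSelector

__all__ = ["STRATEGIES", "make_strategy", "available_methods"]

STRATEGIES: dict[str, Callable[..., InformerStrategy]] = {
    "rs": RegressionSelector,
    "cs": CodingSelector,
    "as": AdaptiveSelector,
    "bc_s": lambda **kw: ChemometricBaseline(expansion="simple", **kw),
    "bc_l": lambda **kw: ChemometricBaseline(expansion="loop", **kw),
    "bc_w": lambda **kw: ChemometricBaseline(expansion="weighted", **kw),
    "bf_s": lambda **kw: FrequentHitterBaseline(expansion="simple", **kw),
    "bf_l": lambda **kw: FrequentHitterBaseline(expansion="loop", **kw),
    "bf_w": lambda **kw: FrequentHitterBaseline(expansion="weighted", **kw),
}


def available_methods() -> list[str]:
    return sorted(STRATEGIES)


def make_strategy(tag: str, **kwargs) -> InformerStrategy:
    """Instantiate a registered strategy; unknown tags raise KeyError."""
    try:
        factory = STRATEGIES[tag]
    except KeyError:
        raise KeyError(
            f"unknown method tag {tag!r}; available: {', '.join(available_methods())}"
        ) from None
    return factory(**kwargs)
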