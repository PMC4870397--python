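"""Registry of gene-set test methods.

A method is a callable ``(dataset, sets, config) -> DataFrame`` with one
row per set and columns ``set_name, method, statistic, p_value, n_perm``.
The built-in methods cover the three self-contained multivariate tests, the
combined-P-value gene-level tests and the competitive enrichment-score
test; new ones can be plugged in with :func:`register_method`.
"""

from __future__ import annotations

from typing import Callable

import pandas as pd

from gsabench._perm import TestConfig
from gsabench.competitive import ssgsea_test_collection
from gsabench.genelevel import CombinationSpec, genelevel_test_collection
from gsabench.selfcontained import (
    mstks_test_collection,
    nstat_test_collection,
    samgs_test_collection,
)
from gsabench.simulate import CountDataset, GeneSetCollection

__all__ = ["register_method", "get_method", "list_methods", "SELF_CONTAINED", "COMPETITIVE"]

MethodFn = Callable[[CountDataset, GeneSetCollection, TestConfig], pd.DataFrame]

_REGISTRY: dict[str, MethodFn] = {}

#: method names by null-hypothesis family (used by reporting helpers)
SELF_CONTAINED = ("nstat", "samgs", "mstks", "fm", "sm", "gm")
COMPETITIVE = ("ssgsea",)


def register_method(name: str, fn: MethodFn, overwrite: bool = False) -> None:
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"method {name!r} is already registered")
    _REGISTRY[name] = fn


def get_method(name: str) -> MethodFn:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; registered methods: {sorted(_REGISTRY)}"
        ) from None


def list_methods() -> list[str]:
    return sorted(_REGISTRY)


def _fm(dataset, sets, config):
    return genelevel_test_collection(dataset, sets, config, spec=CombinationSpec("FM"))


def _sm(dataset, sets, config):
    return genelevel_test_collection(dataset, sets, config, spec=CombinationSpec("SM"))


def _gm(dataset, sets, config):
    return genelevel_test_collection(dataset, sets, config, spec=CombinationSpec("GM"))


register_method("nstat", nstat_test_collection)
register_method("samgs", samgs_test_collection)
register_method("mstks", mstks_test_collection)
register_method("fm", _fm)
register_method("sm", _sm)
register_method("gm", _gm)
register_method("ssgsea", ssgsea_test_collection)
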