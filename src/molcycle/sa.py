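"""Synthetic-accessibility (SA) scoring.

Wraps the Ertl & Schuffenhauer fragment-contribution SA score shipped with
RDKit (``Contrib/SA_Score``). The score ranges from 1 (easy to make) to 10
(very hard); it is the penalty term in penalized logP.
"""

from __future__ import annotations

import importlib.util
import os

from rdkit.Chem import RDConfig

__all__ = ["sa_score", "SAScoreUnavailable"]


class SAScoreUnavailable(RuntimeError):
    """Raised when the RDKit SA_Score contrib module cannot be loaded."""


_sascorer = None


def _load_sascorer():
    global _sascorer
    if _sascorer is None:
        path = os.path.join(RDConfig.RDContribDir, "SA_Score", "sascorer.py")
        if not os.path.exists(path):
            raise SAScoreUnavailable(
                f"RDKit SA_Score contrib module not found at {path}"
            )
        spec = importlib.util.spec_from_file_location("molcycle._sascorer", path)
        module = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(module)
        _sascorer = module
    return _sascorer


def sa_score(mol) -> float:
    """SA score of an RDKit molecule (1 = easy, 10 = hard to synthesize)."""
    try:
        return float(_load_sascorer().calculateScore(mol))
    except SAScoreUnavailable:
        raise
    except Exception as exc:  # fragment contributions undefined for this input
        raise ValueError(f"SA score undefined for molecule: {exc}") from exc
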