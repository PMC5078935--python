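"""Packaged study tables: observed concentrations, individual PK results,
population parameter summaries.

The three CSV fixtures transcribe the published per-patient tables of the
21-patient meropenem ventriculitis cohort:

* table2 — observed serum/CSF concentrations per patient at the 1000 mg
  and 2000 mg q8h dose levels, plus creatinine clearance.  One source cell
  was printed with a comma decimal ("0,62", patient 12 C_min at 1000 mg);
  the fixture stores the normalized 0.62.  Below-LOQ entries keep their
  "<0.5" / "<0.2" tokens.
* table3 — per-patient posterior-median clearance, central volume,
  half-lives, daily AUCs in serum and CSF and the CSF/serum ratio.
* table4 — population mean/median/SD of the seven model parameters.

Fixture files are integrity-checked by SHA-256 before use.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .model import PKParameters

__all__ = [
    "load_table2",
    "load_table3",
    "load_table4",
    "load_fixtures",
    "table3_parameter_sets",
    "table4_median_parameters",
]

_CHECKSUMS = {
    "table2.csv": "c801a67396cd9ad61c0fc6302e3e2ec3d7701552fd48b98bf254943270ea05e3",
    "table3.csv": "9236ea7a448434c6bf84d1bc27f96963faf174d748ca528a2adc537701c68616",
    "table4.csv": "dec8e14c0483571569ead9707f3c75edaf477ff0f8a35308ab35c31f21b6d663",
}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("csfpk.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} failed its integrity check "
            f"(sha256 {digest}, expected {_CHECKSUMS[name]})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), na_values=["NA"], keep_default_na=False)


def load_table2() -> pd.DataFrame:
    """Observed concentrations per patient; '<x' BLQ tokens kept as strings."""
    df = _read("table2.csv")
    if len(df) != 21:
        raise RuntimeError("table2 fixture must have 21 patients")
    return df


def load_table3() -> pd.DataFrame:
    """Per-patient PK results (CL, Vc, half-lives, AUCs, CSF/serum ratio)."""
    df = _read("table3.csv")
    if len(df) != 21:
        raise RuntimeError("table3 fixture must have 21 patients")
    return df


def load_table4() -> pd.DataFrame:
    """Population parameter summary (mean, median, SD), indexed by parameter."""
    df = _read("table4.csv").set_index("parameter")
    if list(df.index) != ["cl", "v_c", "k_cp", "k_pc", "k_cb", "k_bc", "v_csf"]:
        raise RuntimeError("table4 fixture has unexpected parameter rows")
    return df


def load_fixtures() -> dict[str, pd.DataFrame]:
    """All packaged tables as a name -> DataFrame mapping."""
    return {"table2": load_table2(), "table3": load_table3(), "table4": load_table4()}


def table4_median_parameters() -> PKParameters:
    """The population-median parameter vector."""
    med = load_table4()["median"]
    return PKParameters(**{k: float(med[k]) for k in med.index})


def table3_parameter_sets(
    k_cp: float | None = None, k_pc: float | None = None
) -> list[PKParameters]:
    """Reconstruct the 21 per-patient parameter sets from the printed table.

    CL and Vc are printed directly.  The CSF transfer constants come from
    the printed half-lives (k = ln2/t1/2); the apparent CSF volume is
    recovered from the steady-state penetration identity

        AUC_CSF/AUC_serum = (k_cb * Vc) / (k_bc * V_CSF)

    using the printed CSF/serum ratio.  k_cp and k_pc are not printed per
    patient and default to the population medians.  The reconstruction is
    approximate: printed values carry 2-decimal rounding.
    """
    t3 = load_table3()
    med = load_table4()["median"]
    k_cp = float(med["k_cp"]) if k_cp is None else k_cp
    k_pc = float(med["k_pc"]) if k_pc is None else k_pc
    ln2 = np.log(2.0)
    out = []
    for row in t3.itertuples(index=False):
        k_cb = ln2 / row.t_half_cb
        k_bc = ln2 / row.t_half_bc
        v_csf = (k_cb * row.v_c) / (k_bc * row.csf_serum_ratio)
        out.append(
            PKParameters(
                cl=row.cl,
                v_c=row.v_c,
                k_cp=k_cp,
                k_pc=k_pc,
                k_cb=k_cb,
                k_bc=k_bc,
                v_csf=v_csf,
            )
        )
    return out
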