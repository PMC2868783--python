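"""One-shot driver that recomputes the package's reference results.

``reproduce_all`` regenerates, from the model code alone, every printed
anchor the package tracks — the low-pKa species-fraction table, the
midpoint-pH series for diacid and dianion binding, the solubility
quartet, the taurocholate apparent pKa's and ellipticity fit, and the
cyclodextrin bound fraction — and compares each against its packaged
expected value at a stated tolerance.  It is the same battery the
acceptance tests run, exposed as a library call and CLI subcommand.
"""

from __future__ import annotations

from pathlib import Path

from . import binding, cyclodextrin, speciation, taurocholate
from .binding import HostBindingModel, Species
from .io import write_report
from .speciation import HIGH_PKA, LOW_PKA

__all__ = ["reproduce_all", "EXPECTED_FRACTION_TABLE"]

#: Reference low-pKa (4.2/4.9) species fractions, pH 4.0-10.0 step 0.5.
EXPECTED_FRACTION_TABLE = [
    (4.0, 0.5847, 0.3689, 0.0464),
    (4.5, 0.2639, 0.5265, 0.2096),
    (5.0, 0.0656, 0.4137, 0.5208),
    (5.5, 9.96e-03, 0.1988, 0.7913),
    (6.0, 1.17e-03, 0.0735, 0.9253),
    (6.5, 1.23e-04, 0.0245, 0.9753),
    (7.0, 1.25e-05, 7.88e-03, 0.9921),
    (7.5, 1.26e-06, 2.51e-03, 0.9975),
    (8.0, 1.26e-07, 7.94e-04, 0.9992),
    (8.5, 1.26e-08, 2.51e-04, 0.9997),
    (9.0, 1.26e-09, 7.94e-05, 0.9999),
    (9.5, 1.26e-10, 2.51e-05, 0.99997),
    (10.0, 1.26e-10, 7.94e-06, 0.99999),
]

#: (species, K) -> expected midpoint pH under the high pKa pair.
EXPECTED_MIDPOINTS = {
    (Species.H2B, 1e2): 9.251,
    (Species.H2B, 1e3): 9.778,
    (Species.B, 1.0): 8.348,
    (Species.B, 1e1): 7.863,
    (Species.B, 1e2): 7.315,
    (Species.B, 1e3): 6.794,
    (Species.B, 1e4): 6.287,
}
EXPECTED_LIMITING = {Species.H2B: 7.994, Species.B: 8.574}

#: pH -> total solubility (uM) from the partition-derived constants.
EXPECTED_SOLUBILITY = {7.40: 0.062, 7.83: 0.084, 8.05: 0.112, 8.2: 0.148}


def _check(name: str, value: float, expected: float, tol: float, results: dict) -> None:
    ok = abs(value - expected) <= tol
    results["checks"].append(
        {
            "name": name,
            "value": value,
            "expected": expected,
            "tolerance": tol,
            "pass": bool(ok),
        }
    )
    if not ok:
        results["n_failed"] += 1


def reproduce_all(outdir: str | Path | None = None) -> dict:
    """Recompute all tracked reference quantities; optionally write a report.

    Returns a dict with per-check records and an ``n_failed`` count.
    """
    results: dict = {"checks": [], "n_failed": 0}

    # species-fraction table under the low pKa pair
    for ph, eh2b, ehb, eb in EXPECTED_FRACTION_TABLE:
        fr = speciation.species_fractions(ph, LOW_PKA)
        _check(f"fraction_table/pH{ph}/fH2B", fr.fh2b, eh2b, 1e-4, results)
        _check(f"fraction_table/pH{ph}/fHB", fr.fhb, ehb, 1e-4, results)
        _check(f"fraction_table/pH{ph}/fB", fr.fb, eb, 1e-4, results)

    # midpoint-pH series
    for (species, k), expected in EXPECTED_MIDPOINTS.items():
        res = binding.midpoint_ph(HostBindingModel(species, k), HIGH_PKA)
        _check(f"midpoint/{species.value}/K{k:g}", res.ph, expected, 0.01, results)
    for species, expected in EXPECTED_LIMITING.items():
        val = binding.limiting_midpoint(species, HIGH_PKA)
        _check(f"limiting_midpoint/{species.value}", val, expected, 0.01, results)

    # solubility quartet
    for ph, expected in EXPECTED_SOLUBILITY.items():
        _check(
            f"total_solubility/pH{ph}",
            speciation.total_solubility(ph),
            expected,
            1e-3,
            results,
        )

    # taurocholate: apparent pKa's and the ellipticity fit
    dist = taurocholate.MicelleDistribution()
    _check(
        "tc/apparent_pka1",
        taurocholate.apparent_pka(8.12, dist.k_h2b, dist.k_hb),
        7.16,
        0.01,
        results,
    )
    _check(
        "tc/apparent_pka2",
        taurocholate.apparent_pka(8.44, dist.k_hb, dist.k_b),
        6.69,
        0.01,
        results,
    )
    _check(
        "tc/apparent_pka_sum",
        taurocholate.apparent_pka(16.56, dist.k_h2b, dist.k_b),
        13.85,
        0.01,
        results,
    )
    table = taurocholate.load_reference_table()
    fit = taurocholate.fit_ellipticity(
        list(zip(table["fs_hb"], table["fs_b"], table["theta_exp"]))
    )
    _check("tc/fit/A_star", fit.a_star, -98.7, 0.1, results)
    _check("tc/fit/B_star", fit.b_star, 5.24, 0.01, results)
    _check("tc/fit/sd", fit.sd, 1.1, 0.05, results)
    _check("tc/fit/r", fit.r, 0.992, 0.005, results)

    # cyclodextrin bound fraction at the anchor pH
    bound, percent = cyclodextrin.bound_from_affinity()
    _check("cdx/bound_uM", bound, 4.67, 0.005, results)
    _check("cdx/bound_percent", percent, 18.7, 0.05, results)

    results["n_checks"] = len(results["checks"])
    if outdir is not None:
        write_report(results, Path(outdir) / "reproduce_report.json")
    return results
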