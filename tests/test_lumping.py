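"""Lumping rules: aggregate parameters, conservation, exactness limit."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pklump.lumping import (
    LCEN,
    NET,
    LumpingError,
    LumpingScheme,
    build_lumped_odes,
    central_blood_volume,
    default_scheme,
    load_scheme,
    lump_parameters,
    peripheral_volume,
)
from pklump.nca import auc_inf
from pklump.pbpk import (
    build_pbpk_odes,
    default_grid,
    effective_blood_clearance,
    graded_grid,
    simulate,
    suggested_t_end,
)
from pklump.physiology import (
    ALL_COMPARTMENTS,
    BLOOD_COMPARTMENTS,
    NET_TISSUES,
    PERFUSED_TISSUES,
    DrugParameters,
)


def _uniform_kp_drug(kp: float, bp: float = 1.0) -> DrugParameters:
    return DrugParameters(
        name="uniform", fu=0.5, bp=bp, ka=1.0, cl_hep=10.0, cl_ki=1.0,
        kp={t: kp for t in PERFUSED_TISSUES + ("lung",)}, dose=100.0,
    )


class TestSchemes:
    def test_default_scheme_partitions_everything(self):
        s = default_scheme()
        members = set().union(*s.lumps.values()) | set(s.retained)
        assert members == set(ALL_COMPARTMENTS)

    def test_overlapping_scheme_rejected(self):
        with pytest.raises(LumpingError, match="muscle"):
            LumpingScheme(
                lumps={
                    LCEN: frozenset(BLOOD_COMPARTMENTS) | {"lung"},
                    NET: frozenset(NET_TISSUES),
                },
                retained=frozenset(("gut", "spleen", "liver", "kidney", "muscle")),
            )

    def test_incomplete_scheme_rejected(self):
        with pytest.raises(LumpingError, match="missing"):
            LumpingScheme(
                lumps={LCEN: frozenset(BLOOD_COMPARTMENTS) | {"lung"}},
                retained=frozenset(("gut", "spleen", "liver", "kidney")),
            )

    def test_scheme_without_blood_lump_has_no_central(self):
        s = LumpingScheme(
            lumps={"everything": frozenset(t for t in ALL_COMPARTMENTS
                                           if t not in BLOOD_COMPARTMENTS)},
            retained=frozenset(BLOOD_COMPARTMENTS),
        )
        with pytest.raises(LumpingError, match="arterial"):
            _ = s.central

    def test_load_scheme_round_trips_default(self):
        doc = {name: sorted(members) for name, members in default_scheme().lumps.items()}
        doc["retained"] = ["gut", "spleen", "liver", "kidney"]
        assert load_scheme(doc) == default_scheme()


class TestLumpParameters:
    def test_two_tissue_arithmetic(self, phys):
        # Members (V=1, Kp=2) and (V=3, Kp=4): V=4, K=(1*2+3*4)/4=3.5.
        v = dict(phys.volumes)
        v["heart"], v["brain"] = 1.0, 3.0
        phys2 = replace(phys, volumes=v)
        drug = _uniform_kp_drug(1.0)
        kp = dict(drug.kp)
        kp["heart"], kp["brain"] = 2.0, 4.0
        drug = replace(drug, kp=kp)
        scheme = LumpingScheme(
            lumps={
                LCEN: frozenset(BLOOD_COMPARTMENTS) | {"lung"},
                "pair": frozenset(("heart", "brain")),
                NET: frozenset(t for t in NET_TISSUES if t not in ("heart", "brain")),
            },
            retained=frozenset(("gut", "spleen", "liver", "kidney")),
        )
        lp = lump_parameters(phys2, drug, scheme)
        assert lp.volumes["pair"] == pytest.approx(4.0)
        assert lp.kps["pair"] == pytest.approx(3.5)

    def test_single_tissue_lump_is_identity(self, phys, matched_drug):
        scheme = LumpingScheme(
            lumps={
                LCEN: frozenset(BLOOD_COMPARTMENTS) | {"lung"},
                "solo": frozenset(("muscle",)),
                NET: frozenset(t for t in NET_TISSUES if t != "muscle"),
            },
            retained=frozenset(("gut", "spleen", "liver", "kidney")),
        )
        lp = lump_parameters(phys, matched_drug, scheme)
        assert lp.volumes["solo"] == phys.volumes["muscle"]
        assert lp.flows["solo"] == phys.flows["muscle"]
        assert lp.kps["solo"] == pytest.approx(matched_drug.kp["muscle"])

    def test_uniform_kp_gives_uniform_lumped_kp(self, phys):
        lp = lump_parameters(phys, _uniform_kp_drug(2.0), default_scheme())
        assert lp.kps[NET] == pytest.approx(2.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_conservation_on_random_partitions(self, data):
        """V, Q and V*Kp conservation on random partitions of the NET set."""
        from pklump.physiology import default_physiology

        phys = default_physiology()
        tissues = list(NET_TISSUES)
        labels = data.draw(
            st.lists(st.integers(0, 2), min_size=len(tissues), max_size=len(tissues))
        )
        kps = data.draw(
            st.lists(
                st.floats(0.05, 50.0, allow_nan=False),
                min_size=len(tissues),
                max_size=len(tissues),
            )
        )
        drug = _uniform_kp_drug(1.0)
        kp = dict(drug.kp)
        kp.update(dict(zip(tissues, kps)))
        drug = replace(drug, kp=kp)
        groups: dict[str, set] = {}
        for t, g in zip(tissues, labels):
            groups.setdefault(f"g{g}", set()).add(t)
        scheme = LumpingScheme(
            lumps={LCEN: frozenset(BLOOD_COMPARTMENTS) | {"lung"},
                   **{k: frozenset(v) for k, v in groups.items()}},
            retained=frozenset(("gut", "spleen", "liver", "kidney")),
        )
        lp = lump_parameters(phys, drug, scheme)
        names = list(groups)
        assert sum(lp.volumes[g] for g in names) == pytest.approx(
            sum(phys.volumes[t] for t in tissues), rel=1e-12
        )
        assert sum(lp.flows[g] for g in names) == pytest.approx(
            sum(phys.flows[t] for t in tissues), rel=1e-12
        )
        assert sum(lp.volumes[g] * lp.kps[g] for g in names) == pytest.approx(
            sum(phys.volumes[t] * drug.kp[t] for t in tissues), rel=1e-12
        )

    def test_lcen_flow_is_cardiac_output(self, phys, matched_drug):
        lp = lump_parameters(phys, matched_drug, default_scheme())
        assert lp.flows[LCEN] == phys.cardiac_output


class TestLumpedSimulation:
    def test_zero_dose(self, phys, matched_drug):
        drug = replace(matched_drug, dose=0.0)
        res = simulate(build_lumped_odes(phys, drug), default_grid(10.0, 51))
        for series in res.concentrations.values():
            assert np.all(series == 0.0)

    def test_mass_balance(self, phys, matched_drug):
        res = simulate(build_lumped_odes(phys, matched_drug), default_grid(48.0, 201))
        assert res.mass_balance_error() < 1e-6

    def test_exactness_limit(self, phys, matched_drug):
        """All NET tissues sharing one equilibration rate: lumped LCEN tracks
        the full model's venous blood to <0.5% after the absorption onset."""
        grid = default_grid(48.0, 961)
        full = simulate(build_pbpk_odes(phys, matched_drug), grid)
        red = simulate(build_lumped_odes(phys, matched_drug), grid)
        cv, cl = full.concentrations["venous"], red.concentrations[LCEN]
        late = grid >= 1.0
        assert np.max(np.abs(cl[late] - cv[late]) / cv[late]) < 5e-3
        # The first-hour transient (blood transit the reduction removes) is
        # still small relative to the peak.
        assert np.max(np.abs(cl - cv)) < 0.06 * cv.max()

    def test_perturbed_kp_breaks_exactness(self, phys, matched_drug):
        kp = dict(matched_drug.kp)
        kp["muscle"] *= 10.0
        drug = replace(matched_drug, kp=kp)
        grid = default_grid(48.0, 961)
        full = simulate(build_pbpk_odes(phys, drug), grid)
        red = simulate(build_lumped_odes(phys, drug), grid)
        cv, cl = full.concentrations["venous"], red.concentrations[LCEN]
        late = grid >= 1.0
        assert np.max(np.abs(cl[late] - cv[late]) / cv[late]) > 0.05

    def test_clearance_invariance_under_lumping(self, phys, small_panel):
        """Simulated exposure of full and lumped models implies the same
        clearance (identical parametric CL, matching AUC at the blood pool)."""
        for drug in small_panel:
            drug = replace(drug, route="iv_bolus")
            cl_b = effective_blood_clearance(phys, drug)
            grid = graded_grid(suggested_t_end(phys, drug), 1201)
            full = simulate(build_pbpk_odes(phys, drug), grid)
            red = simulate(build_lumped_odes(phys, drug), grid)
            auc_full = auc_inf(grid, full.concentrations["venous"])
            auc_red = auc_inf(grid, red.concentrations[LCEN])
            assert drug.dose / auc_full == pytest.approx(cl_b, rel=0.02)
            assert drug.dose / auc_red == pytest.approx(cl_b, rel=0.02)


class TestPeripheralVolume:
    def test_direct_arithmetic(self, phys, matched_drug):
        # One peripheral tissue V=7, Kp=2, BW=70 -> 0.2 L/kg.
        v = dict(phys.volumes)
        v["muscle"] = 7.0
        phys2 = replace(phys, volumes=v)
        kp = dict(matched_drug.kp)
        kp["muscle"] = 2.0
        drug = replace(matched_drug, kp=kp)
        scheme = LumpingScheme(
            lumps={LCEN: frozenset(BLOOD_COMPARTMENTS) | {"lung"},
                   NET: frozenset(("muscle",))},
            retained=frozenset(t for t in ALL_COMPARTMENTS
                               if t not in BLOOD_COMPARTMENTS
                               and t not in ("lung", "muscle")),
        )
        assert peripheral_volume(phys2, drug, scheme, "pbpk") == pytest.approx(0.2)

    def test_modes_agree_algebraically(self, phys, panel):
        for drug in panel[:8]:
            vp_full = peripheral_volume(phys, drug, model="pbpk")
            vp_lump = peripheral_volume(phys, drug, model="lumped")
            assert vp_full == pytest.approx(vp_lump, rel=1e-12)

    def test_unit_kp_gives_volume_fraction(self, phys):
        drug = _uniform_kp_drug(1.0)
        expected = sum(phys.volumes[t] for t in NET_TISSUES) / phys.body_weight
        assert peripheral_volume(phys, drug, model="pbpk") == pytest.approx(expected)

    def test_central_blood_volume(self, phys):
        drug = _uniform_kp_drug(1.0, bp=2.0)
        expected = (
            phys.volumes["arterial"] + phys.volumes["venous"]
            + phys.volumes["lung"] * 1.0 / 2.0
        ) / phys.body_weight
        assert central_blood_volume(phys, drug) == pytest.approx(expected)
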