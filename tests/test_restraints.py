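import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmr2dock.restraints import (
    AnonymousLabel,
    Restraint,
    RestraintError,
    RestraintNetwork,
    apply_tolerance,
    attach_partial_assignment,
    extract_restraints,
    noe_to_distances,
    read_restraints_tsv,
    write_limit_file,
    write_restraints_tsv,
)
from nmr2dock.structures import MethylSite, ProtonSite


def _site(i, xyz, rtype="ALA", atom="CB"):
    return MethylSite(f"{rtype}{i}-{atom}", i, rtype, atom, np.asarray(xyz, float))


def _proton(pid, xyz):
    return ProtonSite(pid, "", np.asarray(xyz, float))


def test_extract_restraints_distances_and_cutoff():
    protons = [_proton("H1", [0, 0, 0])]
    sites = [_site(1, [0, 0, 4.0]), _site(2, [8.0, 0, 0])]
    net, truth = extract_restraints(protons, sites, max_distance=6.0, seed=0)
    assert len(net) == 1
    assert net.restraints[0].d == pytest.approx(4.0)
    assert net.restraints[0].lower == net.restraints[0].upper == pytest.approx(4.0)
    # the excluded methyl keeps no label
    assert len(net.labels) == 1
    assert truth[net.labels[0].label].site_id == "ALA1-CB"


def test_extract_restraints_count_matches_brute_force():
    rng = np.random.default_rng(5)
    protons = [_proton(f"H{i}", rng.uniform(-3, 3, 3)) for i in range(6)]
    sites = [_site(10 * (i + 1), rng.uniform(-6, 6, 3)) for i in range(5)]
    max_d = 6.5
    net, _ = extract_restraints(protons, sites, max_d, seed=3)
    expected = sum(
        1
        for p in protons for s in sites
        if np.linalg.norm(p.xyz - s.carbon_xyz) <= max_d
    )
    assert len(net) == expected


def test_anonymization_is_pure_relabeling():
    """Different seeds permute labels but preserve the per-site restraint data."""
    rng = np.random.default_rng(8)
    protons = [_proton(f"H{i}", rng.uniform(-3, 3, 3)) for i in range(5)]
    sites = [_site(10 * (i + 1), rng.uniform(-5, 5, 3)) for i in range(4)]

    def site_profile(seed):
        net, truth = extract_restraints(protons, sites, 8.0, seed=seed)
        profile = {}
        for label, site in truth.items():
            rs = frozenset((r.proton_id, round(r.d, 9)) for r in net.restraints_of(label))
            profile[site.site_id] = rs
        return profile

    assert site_profile(1) == site_profile(99)


def test_extract_restraints_same_seed_reproducible():
    rng = np.random.default_rng(2)
    protons = [_proton(f"H{i}", rng.uniform(-3, 3, 3)) for i in range(4)]
    sites = [_site(10 * (i + 1), rng.uniform(-5, 5, 3)) for i in range(3)]
    n1, t1 = extract_restraints(protons, sites, 9.0, seed=7)
    n2, t2 = extract_restraints(protons, sites, 9.0, seed=7)
    assert [(r.label, r.proton_id, r.d) for r in n1.restraints] == \
           [(r.label, r.proton_id, r.d) for r in n2.restraints]
    assert {l: s.site_id for l, s in t1.items()} == {l: s.site_id for l, s in t2.items()}


def test_extract_restraints_empty_network_error():
    with pytest.raises(RestraintError, match="empty network"):
        extract_restraints([_proton("H1", [0, 0, 0])], [_site(1, [10, 0, 0])], 6.0, 0)


@pytest.mark.parametrize(
    "d,fraction,expected",
    [
        (5.0, 0.10, (4.5, 5.5)),
        (5.0, 0.0, (5.0, 5.0)),
        (4.0, 0.20, (3.2, 4.8)),
    ],
)
def test_apply_tolerance_bounds(d, fraction, expected):
    net = RestraintNetwork(
        [Restraint("M_1", "H1", d, d, d)],
        [AnonymousLabel("M_1")],
        [_proton("H1", [0, 0, 0])],
    )
    out = apply_tolerance(net, fraction)
    r = out.restraints[0]
    assert (r.lower, r.upper) == (pytest.approx(expected[0]), pytest.approx(expected[1]))
    assert r.d == pytest.approx(d)


@given(st.floats(0.0, 0.6), st.floats(0.0, 0.6))
def test_tolerance_widens_monotonically(f1, f2):
    net = RestraintNetwork(
        [Restraint("M_1", "H1", 5.0, 5.0, 5.0), Restraint("M_1", "H2", 3.0, 3.0, 3.0)],
        [AnonymousLabel("M_1")],
        [_proton("H1", [0, 0, 0]), _proton("H2", [1, 0, 0])],
    )
    lo, hi = sorted([f1, f2])
    a, b = apply_tolerance(net, lo), apply_tolerance(net, hi)
    for ra, rb in zip(a.restraints, b.restraints):
        assert rb.lower <= ra.lower + 1e-12
        assert rb.upper >= ra.upper - 1e-12


def _toy_network():
    return RestraintNetwork(
        [Restraint("M_1", "H1", 5.0, 5.0, 5.0), Restraint("M_2", "H1", 4.0, 4.0, 4.0)],
        [AnonymousLabel("M_1"), AnonymousLabel("M_2")],
        [_proton("H1", [0, 0, 0])],
    )


def test_attach_partial_assignment():
    net = _toy_network()
    out = attach_partial_assignment(net, {"M_1": {"MET"}}, [("M_1", "M_2")])
    l1 = out.label_by_name("M_1")
    l2 = out.label_by_name("M_2")
    assert l1.type_constraint == frozenset({"MET"})
    assert l1.same_residue_group == l2.same_residue_group is not None
    # identity when nothing is attached
    unchanged = attach_partial_assignment(net)
    assert all(l.type_constraint is None for l in unchanged.labels)
    with pytest.raises(RestraintError, match="unknown label"):
        attach_partial_assignment(net, {"M_9": {"MET"}})


def test_noe_to_distances_ispa():
    times = [0.02, 0.04, 0.06]
    ref_series = [(t, 10.0 * t) for t in times]
    same = [(t, 10.0 * t) for t in times]
    weaker = [(t, 10.0 * t / 64.0) for t in times]
    negative = [(t, -1.0 * t) for t in times]
    out = noe_to_distances(
        {"ref": ref_series, "same": same, "weak": weaker, "neg": negative},
        reference=("ref", 3.0),
    )
    assert out["same"] == pytest.approx(3.0)
    assert out["weak"] == pytest.approx(6.0)  # 64^(1/6) = 2
    assert "neg" not in out


def test_noe_to_distances_scale_invariant():
    times = [0.02, 0.05, 0.08]
    base = {
        "ref": [(t, 7.0 * t) for t in times],
        "p": [(t, 2.0 * t) for t in times],
    }
    scaled = {k: [(t, 100.0 * i) for t, i in v] for k, v in base.items()}
    d1 = noe_to_distances(base, ("ref", 2.5))
    d2 = noe_to_distances(scaled, ("ref", 2.5))
    assert d1["p"] == pytest.approx(d2["p"])


def test_restraints_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    protons = [_proton(f"H{i}", rng.uniform(-3, 3, 3)) for i in range(4)]
    sites = [_site(10 * (i + 1), rng.uniform(-5, 5, 3), "VAL", "CG1") for i in range(3)]
    net, _ = extract_restraints(protons, sites, 9.0, seed=1)
    net = apply_tolerance(net, 0.1)
    net = attach_partial_assignment(net, {"M_1": {"VAL", "LEU", "ILE"}}, [("M_1", "M_2")])
    path = tmp_path / "r.tsv"
    write_restraints_tsv(net, path)
    back = read_restraints_tsv(path, tolerance_fraction=0.1)
    assert [(r.label, r.proton_id) for r in back.restraints] == \
           [(r.label, r.proton_id) for r in net.restraints]
    for a, b in zip(net.restraints, back.restraints):
        assert (a.d, a.lower, a.upper) == pytest.approx((b.d, b.lower, b.upper))
    assert back.label_by_name("M_1").type_constraint == frozenset({"VAL", "LEU", "ILE"})
    assert back.label_by_name("M_1").same_residue_group is not None
    pa = {p.proton_id: p.xyz for p in net.protons}
    pb = {p.proton_id: p.xyz for p in back.protons}
    for pid in pa:
        assert np.allclose(pa[pid], pb[pid], atol=1e-5)


def test_tsv_rejects_inverted_bounds(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "label\tproton_id\td\tlower\tupper\ttype_constraint\tgroup\tpx\tpy\tpz\n"
        "M_1\tH1\t5.0\t5.5\t4.5\t\t\t0\t0\t0\n"
    )
    with pytest.raises(RestraintError, match=":2"):
        read_restraints_tsv(path)


def test_upl_writer_formats_bound(tmp_path):
    net = apply_tolerance(_toy_network(), 0.10)
    upl = tmp_path / "r.upl"
    lol = tmp_path / "r.lol"
    write_limit_file(net, upl, "upl")
    write_limit_file(net, lol, "lol")
    assert "5.50" in upl.read_text()
    assert "4.50" in lol.read_text()
    assert len(upl.read_text().strip().splitlines()) == len(net.restraints)
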