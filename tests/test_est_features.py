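"""Contact counting, solvent accessibility and the empirical delta vector."""

import itertools

import numpy as np
import pytest

from uaatol.est_features import (
    CONTACT_CATEGORIES,
    ContactCounts,
    enumerate_contacts,
    est_delta_vector,
    relative_sasa,
    shrake_rupley_sasa,
)
from uaatol.structures import SiteSelection, Structure

from conftest import build_structure, random_toy_structure


# ---------------------------------------------------------------------------
# independent brute-force oracle


def brute_force_contacts(s, site_key, cutoff=4.0, mixed="polar"):
    """All-pairs contact counting with its own bond-path bookkeeping.

    Bonds are inferred from interatomic distances (<= 1.8 A) within each
    residue; pairs within two bonds are excluded via explicit path
    enumeration.  Intended for unknown-template toys with non-adjacent
    residue numbering (no peptide-junction cases).
    """
    counts = dict.fromkeys(CONTACT_CATEGORIES, 0)
    site_atoms = []
    other_atoms = []
    for r in s.residues:
        (site_atoms if r.key == site_key else other_atoms).extend(r.atoms)
    # bond adjacency within the site residue
    adj = {a.name: set() for a in site_atoms}
    for a, b in itertools.combinations(site_atoms, 2):
        if np.linalg.norm(a.coords - b.coords) <= 1.8:
            adj[a.name].add(b.name)
            adj[b.name].add(a.name)

    def within_two_bonds(a, b):
        if b.name in adj[a.name]:
            return True
        return any(b.name in adj[m] for m in adj[a.name])

    def record(a, b, loc):
        pair = (
            "bb_bb"
            if a.is_backbone and b.is_backbone
            else "sc_sc"
            if not a.is_backbone and not b.is_backbone
            else "bb_sc"
        )
        both_np = a.polarity == "nonpolar" and b.polarity == "nonpolar"
        both_p = a.polarity == "polar" and b.polarity == "polar"
        pol = "np" if both_np or (not both_p and mixed == "nonpolar") else "p"
        counts[f"{pol}_{pair}_{loc}"] += 1

    for a, b in itertools.combinations(site_atoms, 2):
        if within_two_bonds(a, b):
            continue
        if np.linalg.norm(a.coords - b.coords) < cutoff:
            record(a, b, "intra")
    for a in site_atoms:
        for b in other_atoms:
            if np.linalg.norm(a.coords - b.coords) < cutoff:
                record(a, b, "inter")
    return counts


class TestEnumerateContacts:
    def test_no_pairs_within_cutoff_gives_zero(self):
        s = build_structure(
            [
                (("A", 1), "GLY", [("CA", "C", [0, 0, 0])]),
                (("A", 9), "GLY", [("CA", "C", [50, 0, 0])]),
            ]
        )
        counts = enumerate_contacts(s, SiteSelection(("A", 1)))
        assert counts.total_contacts == 0
        assert all(getattr(counts, c) == 0 for c in CONTACT_CATEGORIES)

    def test_single_planted_np_sc_sc_inter_contact(self):
        # one sidechain C pair at 3.5 A; every other pair way beyond 4 A
        s = build_structure(
            [
                (("A", 1), "LIG", [("CA", "C", [0, 0, 0]), ("C1", "C", [20, 0, 0])]),
                (("A", 9), "LIG", [("CA", "C", [40, 0, 0]), ("C1", "C", [23.5, 0, 0])]),
            ]
        )
        counts = enumerate_contacts(s, SiteSelection(("A", 1)))
        assert counts.np_sc_sc_inter == 1
        assert counts.total_np_contacts == 1
        assert counts.total_contacts == 1
        assert sum(getattr(counts, c) for c in CONTACT_CATEGORIES) == 1
        # cross-check against the independent oracle
        assert counts.as_dict() | brute_force_contacts(s, ("A", 1)) == counts.as_dict()

    def test_boundary_at_exactly_cutoff_excluded(self):
        s = build_structure(
            [
                (("A", 1), "LIG", [("C1", "C", [0, 0, 0])]),
                (("A", 9), "LIG", [("C1", "C", [4.0, 0, 0])]),
            ]
        )
        assert enumerate_contacts(s, SiteSelection(("A", 1))).total_contacts == 0

    def test_atom_order_permutation_invariance(self):
        rng = np.random.default_rng(11)
        s = random_toy_structure(rng, n_residues=4)
        site = SiteSelection(s.residues[1].key)
        base = enumerate_contacts(s, site).as_dict()
        shuffled = Structure(
            id="perm",
            residues=[
                type(r)(key=r.key, aa_code=r.aa_code,
                        atoms=list(reversed(r.atoms)))
                for r in reversed(s.residues)
            ],
        )
        assert enumerate_contacts(shuffled, site).as_dict() == base

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        s = random_toy_structure(rng)
        site = SiteSelection(s.residues[rng.integers(len(s.residues))].key)
        got = enumerate_contacts(s, site).as_dict()
        expect = brute_force_contacts(s, site.residue_key)
        assert {k: got[k] for k in CONTACT_CATEGORIES} == expect

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(5)
        s = random_toy_structure(rng, n_residues=5)
        site = SiteSelection(s.residues[2].key)
        base = enumerate_contacts(s, site).as_dict()
        rot = Rotation.random(random_state=3).as_matrix()
        moved = build_structure(
            [
                (r.key, r.aa_code,
                 [(a.name, a.element, rot @ a.coords + [3, -7, 11]) for a in r.atoms])
                for r in s.residues
            ]
        )
        assert enumerate_contacts(moved, site).as_dict() == base

    def test_peptide_junction_pairs_excluded(self):
        # only the site C / next-residue N pair lies within 4 A: it is the
        # peptide bond, so it must not count as a contact
        s = build_structure(
            [
                (("A", 1), "GLY", [
                    ("N", "N", [-30, 0, 0]), ("CA", "C", [-20, 0, 0]),
                    ("C", "C", [0, 0, 0]), ("O", "O", [-10, 10, 0]),
                ]),
                (("A", 2), "GLY", [
                    ("N", "N", [1.33, 0, 0]), ("CA", "C", [20, 10, 0]),
                    ("C", "C", [30, 0, 0]), ("O", "O", [40, -10, 0]),
                ]),
            ]
        )
        site = SiteSelection(("A", 1))
        assert enumerate_contacts(s, site).total_contacts == 0
        counts_raw = enumerate_contacts(s, site, exclude_bonded=False)
        assert counts_raw.p_bb_bb_inter == 1
        assert counts_raw.total_contacts == 1


class TestShrakeRupley:
    def test_isolated_carbon_matches_analytic_sphere(self):
        s = build_structure([(("A", 1), "LIG", [("C1", "C", [0, 0, 0])])])
        area = shrake_rupley_sasa(s)[("A", 1)]
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.02)

    def test_distant_atoms_are_additive(self):
        s = build_structure(
            [
                (("A", 1), "LIG", [("C1", "C", [0, 0, 0])]),
                (("A", 9), "LIG", [("O1", "O", [100, 0, 0])]),
            ]
        )
        areas = shrake_rupley_sasa(s)
        a_c = 4 * np.pi * (1.7 + 1.4) ** 2
        a_o = 4 * np.pi * (1.52 + 1.4) ** 2
        assert areas[("A", 1)] == pytest.approx(a_c, rel=0.02)
        assert areas[("A", 9)] == pytest.approx(a_o, rel=0.02)

    def test_two_overlapping_spheres_match_monte_carlo_oracle(self):
        d = 2.5
        s = build_structure(
            [
                (("A", 1), "LIG", [("C1", "C", [0, 0, 0])]),
                (("A", 9), "LIG", [("C1", "C", [d, 0, 0])]),
            ]
        )
        total = sum(shrake_rupley_sasa(s).values())
        # Monte-Carlo surface sampling oracle (independent of the
        # deterministic golden-spiral implementation)
        rng = np.random.default_rng(42)
        n = 200_000
        r = 1.7 + 1.4
        centers = np.array([[0.0, 0, 0], [d, 0, 0]])
        mc_total = 0.0
        for c in centers:
            pts = rng.standard_normal((n, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = c + r * pts
            other = centers[1] if np.allclose(c, centers[0]) else centers[0]
            outside = np.linalg.norm(pts - other, axis=1) > r
            mc_total += 4 * np.pi * r**2 * outside.mean()
        assert total == pytest.approx(mc_total, rel=0.03)

    def test_matches_biopython_shrake_rupley(self, helix):
        """Cross-check against Bio.PDB's independent implementation."""
        import io

        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        from uaatol.structures import to_pdb

        ours = shrake_rupley_sasa(helix)
        model = PDBParser(QUIET=True).get_structure("h", io.StringIO(to_pdb(helix)))
        sr = ShrakeRupley(probe_radius=1.4, n_points=960)
        sr.compute(model[0], level="R")
        for chain in model[0]:
            for res in chain:
                key = ("A", res.get_id()[1])
                assert ours[key] == pytest.approx(res.sasa, rel=0.05, abs=1.0)


class TestRelativeSasa:
    def test_ratio_rules(self):
        assert relative_sasa(104.0, "GLY") == pytest.approx(1.0)
        assert relative_sasa(0.0, "GLY") == 0.0
        assert relative_sasa(52.0, "GLY") == pytest.approx(0.5)

    def test_unknown_code_errors(self):
        with pytest.raises(KeyError):
            relative_sasa(10.0, "ACD")


class TestEstDeltaVector:
    def test_identical_pair_all_zero(self, helix, helix_site):
        vec = est_delta_vector(helix, helix, helix_site, n_sphere_points=120)
        assert all(vec.deltas[c] == 0 for c in CONTACT_CATEGORIES)
        assert vec.deltas["total_contacts"] == 0
        assert vec.asa > 0

    def test_planted_single_contact_delta(self):
        base = [
            (("A", 1), "LIG", [("CA", "C", [0, 0, 0]), ("C1", "C", [20, 0, 0])]),
            (("A", 9), "LIG", [("CA", "C", [40, 0, 0]), ("C1", "C", [60, 0, 0])]),
        ]
        wt = build_structure(base)
        mutant = build_structure(
            [
                (("A", 1), "LIG", [("CA", "C", [0, 0, 0]), ("C1", "C", [56.5, 0, 0])]),
                base[1],
            ]
        )
        vec = est_delta_vector(wt, mutant, SiteSelection(("A", 1)), n_sphere_points=120)
        assert vec.deltas["np_sc_sc_inter"] == 1
        assert vec.deltas["total_contacts"] == 1
        assert vec.deltas["total_np_contacts"] == 1

    def test_swap_negates_all_deltas(self, helix, helix_site):
        from uaatol.synthetic_data import make_bulky_mutant

        with pytest.warns(UserWarning):
            mut = make_bulky_mutant(helix, helix_site, 10)
        fwd = est_delta_vector(helix, mut, helix_site, n_sphere_points=120)
        # reverse direction: accessibility changes (taken from the first
        # argument) but every contact delta must flip sign
        rev = est_delta_vector(mut, helix, helix_site, n_sphere_points=120)
        for c in CONTACT_CATEGORIES:
            assert rev.deltas[c] == -fwd.deltas[c]

    def test_differences_away_from_site_rejected(self, helix, helix_site):
        import copy

        other = copy.deepcopy(helix)
        atoms = other.residues[0].atoms
        moved = atoms[0]
        from uaatol.structures import Atom

        atoms[0] = Atom(moved.name, moved.element, moved.coords + 1.0,
                        moved.residue_key, moved.is_backbone, moved.polarity)
        with pytest.raises(ValueError, match=r"\('A', 1\)"):
            est_delta_vector(helix, other, helix_site, n_sphere_points=60)

    def test_total_deltas_equal_sum_of_categories(self, helix, helix_site):
        from uaatol.synthetic_data import make_bulky_mutant

        with pytest.warns(UserWarning):
            mut = make_bulky_mutant(helix, helix_site, 12)
        vec = est_delta_vector(helix, mut, helix_site, n_sphere_points=60)
        assert vec.deltas["total_contacts"] == sum(
            vec.deltas[c] for c in CONTACT_CATEGORIES
        )
        assert vec.deltas["total_np_contacts"] == sum(
            vec.deltas[c] for c in CONTACT_CATEGORIES if c.startswith("np_")
        )


def test_contact_counts_invariants():
    c = ContactCounts(np_bb_sc_intra=2, p_sc_sc_inter=3, np_sc_sc_inter=1)
    assert c.total_contacts == c.total_np_contacts + c.total_p_contacts == 6
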