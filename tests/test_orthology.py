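"""RBH validation, iterative seed growth, and presence matrices."""

import math

import pytest

from strucfind.backends import NaiveBackend, PyhmmerBackend
from strucfind.hhr_io import BlastHit
from strucfind.orthology import (
    EVALUE_FLOOR,
    OrthologyCall,
    iterative_search,
    presence_matrix,
    rbh_validate,
)


def bhit(subject, e):
    return BlastHit("cand", subject, 50.0, 100, 10, 0, 1, 100, 1, 100, e, 100.0)


def hit_list(*pairs):
    return [bhit(s, e) for s, e in pairs]


# ---------------------------------------------------------------------------
# brute-force reference for the RBH verdict
# ---------------------------------------------------------------------------

def brute_force_rbh(reference_hits, expected, margin_orders=2.0):
    def log10e(e):
        return math.log10(max(e, EVALUE_FLOOR))

    for ref, hits in reference_hits.items():
        if not hits:
            continue
        if hits[0].subject_id != expected[ref]:
            continue
        if len(hits) == 1:
            return True
        if log10e(hits[1].e_value) - log10e(hits[0].e_value) >= margin_orders:
            return True
    return False


class TestRbhValidate:
    def test_boundary_pass_at_exactly_two_orders(self):
        refs = {"at": hit_list(("ORTH", 1e-12), ("other", 1e-10))}
        call = rbh_validate("cand", refs, {"at": "ORTH"})
        assert call.found
        assert call.margin == pytest.approx(2.0)
        assert call.rbh_reference == "at"

    def test_fail_at_one_order(self):
        refs = {"at": hit_list(("ORTH", 1e-12), ("other", 1e-11))}
        assert not rbh_validate("cand", refs, {"at": "ORTH"}).found

    def test_wrong_best_hit_fails_everywhere(self):
        refs = {
            "at": hit_list(("paralog", 1e-30), ("ORTH", 1e-5)),
            "dd": hit_list(("junk", 1e-8), ("ORTH2", 1e-2)),
        }
        call = rbh_validate("cand", refs, {"at": "ORTH", "dd": "ORTH2"})
        assert call.status == "not_found"

    def test_one_passing_reference_suffices(self):
        refs = {
            "at": hit_list(("paralog", 1e-30), ("ORTH", 1e-5)),
            "dd": hit_list(("ORTH2", 1e-20), ("junk", 1e-3)),
        }
        call = rbh_validate("cand", refs, {"at": "ORTH", "dd": "ORTH2"})
        assert call.found and call.rbh_reference == "dd"

    def test_single_hit_passes_vacuously_with_flag(self):
        call = rbh_validate("cand", {"at": hit_list(("ORTH", 1e-12))}, {"at": "ORTH"})
        assert call.found and "single_hit" in call.flags
        strict = rbh_validate(
            "cand", {"at": hit_list(("ORTH", 1e-12))}, {"at": "ORTH"}, strict_single_hit=True
        )
        assert not strict.found

    def test_zero_evalue_floored_and_flagged(self):
        call = rbh_validate("cand", {"at": hit_list(("ORTH", 0.0), ("other", 1e-20))}, {"at": "ORTH"})
        assert call.found and "evalue_floored" in call.flags
        assert call.margin == pytest.approx(160.0)

    def test_missing_expected_entry_is_error(self):
        with pytest.raises(ValueError, match="ng"):
            rbh_validate("cand", {"ng": hit_list(("x", 1e-5))}, {"at": "ORTH"})

    def test_margin_invariant_under_uniform_scaling(self):
        base = {"at": hit_list(("ORTH", 1e-12), ("other", 1e-9))}
        for factor in (1e-6, 1e-3, 1.0, 1e3):
            scaled = {"at": hit_list(("ORTH", 1e-12 * factor), ("other", 1e-9 * factor))}
            a = rbh_validate("cand", base, {"at": "ORTH"})
            b = rbh_validate("cand", scaled, {"at": "ORTH"})
            assert a.found == b.found
            assert b.margin == pytest.approx(a.margin)

    def test_verdict_depends_only_on_top_two_hits(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 8))
            es = sorted(10.0 ** rng.uniform(-60, 0, size=n))
            subjects = ["ORTH" if rng.random() < 0.5 else "other0"] + [f"other{i}" for i in range(1, n)]
            full = {"at": hit_list(*zip(subjects, es))}
            top2 = {"at": hit_list(*zip(subjects[:2], es[:2]))}
            assert (
                rbh_validate("c", full, {"at": "ORTH"}).found
                == rbh_validate("c", top2, {"at": "ORTH"}).found
            )

    def test_oracle_equivalence_1000_random_tables(self, rng):
        for _ in range(1000):
            refs = {}
            expected = {}
            for r in range(int(rng.integers(1, 4))):
                ref = f"ref{r}"
                n = int(rng.integers(0, 6))
                es = sorted(10.0 ** rng.uniform(-40, 1, size=n))
                subs = [
                    "ORTH" if rng.random() < 0.4 else f"bg{int(rng.integers(0, 5))}{i}"
                    for i in range(n)
                ]
                refs[ref] = hit_list(*zip(subs, es))
                expected[ref] = "ORTH"
            verdict = rbh_validate("c", refs, expected).found
            assert verdict == brute_force_rbh(refs, expected)


# ---------------------------------------------------------------------------
# iterative search on the simulated gradient
# ---------------------------------------------------------------------------

class TestIterativeSearch:
    def test_lost_member_is_not_found(self, genome_fixture, orthology_runs):
        found = {(c.taxon, c.family) for c in orthology_runs["iterative"] if c.found}
        for taxon, family in genome_fixture.loss_pattern:
            assert (taxon, family) not in found

    def test_found_candidates_are_the_planted_accessions(self, genome_fixture, orthology_runs):
        planted = genome_fixture.planted_ids
        for c in orthology_runs["iterative"]:
            if c.found:
                assert c.candidate_id == planted[(c.taxon, c.family)]

    def test_iterative_recovers_at_least_static_count(self, orthology_runs):
        n_iter = sum(c.found for c in orthology_runs["iterative"])
        n_static = sum(c.found for c in orthology_runs["static"])
        assert n_iter >= n_static

    def test_backend_failure_recorded_not_fatal(self, genome_fixture):
        class ExplodingBackend:
            def search(self, queries, proteome):
                raise RuntimeError("boom")

        family = next(iter(genome_fixture.seed_sets))
        calls = iterative_search(
            genome_fixture.seed_sets[family],
            genome_fixture.genomes[:2],
            ExplodingBackend(),
            genome_fixture.references,
            genome_fixture.expected[family],
            family=family,
        )
        assert len(calls) == 2
        assert all(c.status == "not_found" and "backend error" in c.note for c in calls)

    def test_empty_seed_set_rejected(self, genome_fixture):
        with pytest.raises(ValueError):
            iterative_search([], genome_fixture.genomes, NaiveBackend(), {}, {})

    def test_pyhmmer_backend_finds_planted_member(self, genome_fixture):
        """The real profile-HMM backend agrees with the naive one on an
        easy cell: the planted member is the top hit."""
        family = next(iter(genome_fixture.seed_sets))
        taxon, proteome = genome_fixture.genomes[0]
        if (taxon, family) in genome_fixture.loss_pattern:
            taxon, proteome = genome_fixture.genomes[1]
        hits = PyhmmerBackend().search(genome_fixture.seed_sets[family], proteome)
        assert hits[0].subject_id == genome_fixture.planted_ids[(taxon, family)]


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

def call(f, t, status):
    kwargs = {"candidate_id": "x", "rbh_reference": "at", "margin": 5.0} if status == "found" else {}
    return OrthologyCall(family=f, taxon=t, status=status, **kwargs)


class TestPresenceMatrix:
    def test_two_by_two_with_one_absence(self):
        calls = [
            call("F1", "t1", "found"),
            call("F2", "t1", "found"),
            call("F1", "t2", "found"),
            call("F2", "t2", "not_found"),
        ]
        m = presence_matrix(calls)
        assert len(m.cells) == 4
        assert sum(v for v in m.cells.values()) == 3
        assert m.complete_taxa == ("t1",)
        assert m.to_csv() == "taxon,F1,F2\nt1,1,1\nt2,1,0\n"

    def test_missing_cell_is_error(self):
        calls = [call("F1", "t1", "found"), call("F2", "t2", "found")]
        with pytest.raises(ValueError, match="missing"):
            presence_matrix(calls)

    def test_cell_count_always_full_grid(self, orthology_runs):
        m = presence_matrix(orthology_runs["iterative"])
        assert len(m.cells) == len(m.taxa) * len(m.families)

    def test_plot_renders_full_glyph_grid(self, orthology_runs):
        import matplotlib

        matplotlib.use("Agg")
        m = presence_matrix(orthology_runs["iterative"])
        ax = m.plot()
        # one wedge per cell
        assert len(ax.patches) == len(m.taxa) * len(m.families)

    def test_matrix_reproduces_planted_loss_pattern(self, genome_fixture, orthology_runs):
        """End-to-end: the presence matrix equals the generator's planted
        loss pattern cell for cell."""
        m = presence_matrix(orthology_runs["iterative"])
        for t in m.taxa:
            for f in m.families:
                expected_present = (t, f) not in genome_fixture.loss_pattern
                assert m.cells[(t, f)] == expected_present, (t, f)
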