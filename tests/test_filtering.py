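"""Threshold acceptance, classification, blocklisting and whole-read removal."""

import pytest

from ccsfilt.aligner import AdapterHit
from ccsfilt.filtering import (
    FilterConfig,
    build_blocklist,
    classify_read,
    effective_report_floor,
    filter_reads,
    hit_passes,
)
from ccsfilt.io_formats import SeqRead, write_sequences
from conftest import random_read


def make_hit(
    read_id="r",
    adapter_name="pacbio_blunt_adapter",
    read_start=0,
    columns=45,
    matches=45,
    orientation="forward",
):
    mismatches = columns - matches
    return AdapterHit(
        read_id=read_id,
        adapter_name=adapter_name,
        orientation=orientation,
        read_start=read_start,
        read_end=read_start + columns,
        adapter_start=0,
        adapter_end=columns,
        score=matches - 5 * mismatches,
        alignment_columns=columns,
        matches=matches,
        mismatches=mismatches,
        gap_opens=0,
    )


class TestHitPasses:
    @pytest.mark.parametrize(
        "columns,matches,expected",
        [
            (45, 45, True),   # perfect full-length
            (44, 44, True),   # one missing base
            (45, 44, True),   # one substitution: 97.78% >= 97
            (43, 43, False),  # too short despite 100% identity
            (45, 43, False),  # 95.56% < 97
            (44, 42, False),  # short of identity
        ],
    )
    def test_blunt_adapter_defaults(self, blunt, columns, matches, expected):
        hit = make_hit(columns=columns, matches=matches)
        assert hit_passes(hit, blunt, FilterConfig()) is expected

    @pytest.mark.parametrize("columns,expected", [(35, True), (34, True), (33, False)])
    def test_c2_primer_has_its_own_length_default(self, c2, columns, expected):
        hit = make_hit(adapter_name="pacbio_c2_primer", columns=columns, matches=columns)
        assert hit_passes(hit, c2, FilterConfig()) is expected

    def test_overrides_apply_uniformly(self, blunt, c2):
        config = FilterConfig(min_match_length_override=30, min_identity_override=90.0)
        weak = make_hit(columns=33, matches=31)  # 93.9% over 33 columns
        assert hit_passes(weak, blunt, config)
        weak_c2 = make_hit(adapter_name="pacbio_c2_primer", columns=30, matches=28)
        assert hit_passes(weak_c2, c2, config)

    def test_mismatched_adapter_record_is_an_error(self, c2):
        with pytest.raises(ValueError):
            hit_passes(make_hit(), c2, FilterConfig())


class TestClassifyRead:
    def test_five_prime(self):
        cls = classify_read(10_000, [make_hit(read_start=0)])
        assert cls.category == "five_prime" and cls.n_hits == 1

    def test_internal(self):
        assert classify_read(10_000, [make_hit(read_start=5000)]).category == "internal"

    def test_three_prime(self):
        assert classify_read(10_000, [make_hit(read_start=9900)]).category == "three_prime"

    def test_distributed_when_zones_differ(self):
        hits = [make_hit(read_start=50), make_hit(read_start=9900)]
        assert classify_read(10_000, hits).category == "distributed"

    def test_same_zone_multiple_hits_keeps_zone(self):
        hits = [make_hit(read_start=0), make_hit(read_start=100)]
        assert classify_read(10_000, hits).category == "five_prime"

    def test_both_end_zones_on_short_read_counts_as_five_prime(self):
        # a 45-column hit on a 120 bp read starts in the 5' zone and ends in
        # the 3' zone; coverage stays below the dimer threshold
        cls = classify_read(120, [make_hit(read_start=5)])
        assert cls.category == "five_prime"

    def test_adapter_dimer_like_reads_are_other(self):
        hits = [make_hit(read_start=0), make_hit(read_start=45)]
        assert classify_read(100, hits).category == "other"

    def test_orientation_multiset(self):
        hits = [make_hit(read_start=0), make_hit(read_start=200, orientation="reverse")]
        cls = classify_read(10_000, hits)
        assert cls.orientations == {"forward": 1, "reverse": 1}

    def test_empty_hits_rejected(self):
        with pytest.raises(ValueError):
            classify_read(1000, [])


class TestBuildBlocklist:
    def test_clean_reads_yield_empty_blocklist(self, adapters, rng):
        reads = [random_read(rng, 10_000, f"clean{i}") for i in range(10)]
        blocklist, hits, classifications = build_blocklist(reads, adapters)
        assert blocklist == set() and hits == [] and classifications == []

    def test_spiked_reads_are_blocklisted(self, adapters, rng):
        reads = [random_read(rng, 5000, f"r{i}") for i in range(10)]
        for i in (1, 4, 7):
            seq = reads[i].sequence
            reads[i] = SeqRead(
                reads[i].read_id,
                seq[:2000] + adapters[0].sequence + seq[2045:],
                quality=reads[i].quality,
            )
        blocklist, hits, classifications = build_blocklist(reads, adapters)
        assert blocklist == {"r1", "r4", "r7"}
        assert len(classifications) == 3
        assert all(c.category == "internal" for c in classifications)

    def test_43bp_fragment_not_blocklisted_at_defaults(self, adapters, rng):
        from conftest import embed_fragment

        read = random_read(rng, 5000, "frag")
        fragment = adapters[0].sequence[:43]
        seq = embed_fragment(read.sequence, fragment, 1000, adapters[0].sequence)
        blocklist, _, _ = build_blocklist(
            [SeqRead("frag", seq, quality=read.quality)], adapters
        )
        assert blocklist == set()

    def test_duplicate_read_ids_fatal(self, adapters, rng):
        reads = [random_read(rng, 600, "dup"), random_read(rng, 600, "dup")]
        with pytest.raises(ValueError, match="dup"):
            build_blocklist(reads, adapters)


class TestEffectiveReportFloor:
    def test_defaults_keep_standard_floor(self, adapters):
        assert effective_report_floor(adapters, FilterConfig()) == 20

    def test_relaxed_thresholds_lower_the_floor(self, adapters):
        config = FilterConfig(min_match_length_override=30, min_identity_override=90.0)
        # 27 matches minimum, 3 non-match columns at worst 6 points each
        assert effective_report_floor(adapters, config) == 9


class TestFilterReads:
    @pytest.fixture()
    def fastq(self, tmp_path, rng):
        reads = [random_read(rng, 200, f"k{i}") for i in range(10)]
        path = tmp_path / "pool.fastq"
        write_sequences(reads, path, format="fastq")
        return path

    def test_conservation_and_byte_identity(self, tmp_path, fastq):
        out = tmp_path / "pool.filt.fastq"
        kept, removed = filter_reads(fastq, {"k2", "k5", "k9"}, out)
        assert (kept, removed) == (7, 3)
        expected = [
            block
            for block in fastq.read_text().split("@")[1:]
            if block.split()[0] not in {"k2", "k5", "k9"}
        ]
        assert out.read_text() == "".join("@" + b for b in expected)

    def test_empty_blocklist_is_identity(self, tmp_path, fastq):
        out = tmp_path / "same.fastq"
        kept, removed = filter_reads(fastq, set(), out)
        assert (kept, removed) == (10, 0)
        assert out.read_bytes() == fastq.read_bytes()

    def test_full_blocklist_annihilates(self, tmp_path, fastq):
        out = tmp_path / "none.fastq"
        kept, removed = filter_reads(fastq, {f"k{i}" for i in range(10)}, out)
        assert (kept, removed) == (0, 10)
        assert out.read_text() == ""

    def test_missing_blocklist_id_warns(self, tmp_path, fastq, caplog):
        out = tmp_path / "w.fastq"
        with caplog.at_level("WARNING"):
            kept, removed = filter_reads(fastq, {"k1", "ghost"}, out)
        assert (kept, removed) == (9, 1)
        assert "not found" in caplog.text

    def test_exact_id_matching_no_prefix_collisions(self, tmp_path, rng):
        # 'k1' must not remove 'k10' (the grep failure mode)
        reads = [random_read(rng, 100, rid) for rid in ("k1", "k10")]
        path = tmp_path / "ids.fastq"
        write_sequences(reads, path, format="fastq")
        out = tmp_path / "ids.filt.fastq"
        kept, removed = filter_reads(path, {"k1"}, out)
        assert (kept, removed) == (1, 1)
        assert "@k10" in out.read_text()


def test_blocklist_monotone_in_thresholds(adapters, rng):
    """Relaxing -l/-m never shrinks the blocklist; tightening never grows it."""
    reads = [random_read(rng, 2000, f"bg{i}") for i in range(10)]
    variants = []
    blunt = adapters[0].sequence
    degrade = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for i, n_subs in enumerate([0, 1, 2, 3, 5]):
        base = random_read(rng, 2000, f"deg{i}_{n_subs}")
        copy = list(blunt)
        for k in range(n_subs):
            pos = 4 + 8 * k
            copy[pos] = degrade[copy[pos]]
        seq = base.sequence[:900] + "".join(copy) + base.sequence[945:]
        variants.append(SeqRead(base.read_id, seq, quality=base.quality))
    from conftest import embed_fragment

    for j, frag_len in enumerate([30, 35, 40, 43]):
        base = random_read(rng, 2000, f"frag{j}_{frag_len}")
        seq = embed_fragment(base.sequence, blunt[:frag_len], 500, blunt)
        variants.append(SeqRead(base.read_id, seq, quality=base.quality))
    pool = reads + variants
    sizes = {}
    for min_len in (30, 40, 44):
        for min_ident in (90.0, 95.0, 97.0, 99.0):
            config = FilterConfig(
                min_match_length_override=min_len, min_identity_override=min_ident
            )
            blocklist, _, _ = build_blocklist(pool, adapters, config=config)
            sizes[(min_len, min_ident)] = len(blocklist)
    for min_ident in (90.0, 95.0, 97.0, 99.0):
        assert sizes[(30, min_ident)] >= sizes[(40, min_ident)] >= sizes[(44, min_ident)]
    for min_len in (30, 40, 44):
        assert (
            sizes[(min_len, 90.0)]
            >= sizes[(min_len, 95.0)]
            >= sizes[(min_len, 97.0)]
            >= sizes[(min_len, 99.0)]
        )
    assert sizes[(30, 90.0)] > sizes[(44, 99.0)]  # the grid is not degenerate
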