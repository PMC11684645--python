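import textwrap

import pytest

from mhtrends.registry_io import TrialRecord


def make_study_xml(nct_id="NCT00000001", status="Completed",
                   start_date="June 2015", brief=None, detailed=None) -> str:
    parts = [f"<clinical_study>",
             f"  <id_info><nct_id>{nct_id}</nct_id></id_info>",
             f"  <overall_status>{status}</overall_status>"]
    if start_date is not None:
        parts.append(f"  <start_date>{start_date}</start_date>")
    if brief is not None:
        parts.append(f"  <brief_summary><textblock>{brief}</textblock></brief_summary>")
    if detailed is not None:
        parts.append(
            f"  <detailed_description><textblock>{detailed}</textblock></detailed_description>")
    parts.append("</clinical_study>")
    return "\n".join(parts)


@pytest.fixture
def xml_dir(tmp_path):
    """Directory of 12 hand-specified study records: 9 includable, 3 not."""
    specs = [
        ("NCT00000001", "Completed", "June 2015", "Anxiety study.", "More detail."),
        ("NCT00000002", "Recruiting", "March 3, 2021", "A depression trial.", None),
        ("NCT00000003", "Active, not recruiting", "January 2020", None, "distress here"),
        ("NCT00000004", "Enrolling by invitation", "2019-07", "loneliness", "text"),
        ("NCT00000005", "Completed", "May 1998", "no terms at all", "filler words"),
        ("NCT00000006", "COMPLETED", "December 2022", "anxiety-related decoy", None),
        ("NCT00000007", "Recruiting", "April 2020", "patient's anxiety", None),
        ("NCT00000008", "Completed", "August 2010", "depression depression", "anxiety"),
        ("NCT00000009", "Active, Not Recruiting", "July 2021", "Alzheimer's disease", None),
        ("NCT00000010", "Withdrawn", "June 2018", "anxiety", None),
        ("NCT00000011", "Terminated", "June 2017", "depression", None),
        ("NCT00000012", "Unknown status", "June 2016", None, None),
    ]
    for nct, status, date, brief, detailed in specs:
        (tmp_path / f"{nct}.xml").write_text(
            make_study_xml(nct, status, date, brief, detailed))
    return tmp_path


@pytest.fixture
def record():
    return TrialRecord(
        nct_id="NCT01234567", overall_status="Completed", start_date="June 2019",
        brief_description="Anxiety study.",
        detailed_description=textwrap.dedent("""\
            This trial measures distress, anxiety and the patient's depression
            over 12 weeks."""))
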