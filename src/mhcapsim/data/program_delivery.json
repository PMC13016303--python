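[
  {
    "program": "CASA Mental Health (Youth)",
    "planned_description": "Establish 6 additional classrooms; $30M funding for expansion toward 60 classrooms by 2026; $14M for CASA Houses to serve up to 324 youth/year once operational",
    "metrics": [
      {"unit": "students", "actual": 96},
      {"unit": "classrooms", "planned": 6, "actual": 6}
    ],
    "outcome_note": "6 classrooms added (total 8 operational); 647 unique clients in Core programs (417 new); >690 referrals",
    "source_note": "Pages 43-47: Focus on classrooms and Core programs; no session-based metric, so use clients/students."
  },
  {
    "program": "VODP (Addiction Care)",
    "planned_description": "$11.2M funding for continued operation and expansion to 24/7 in 2024-25; no specific numeric target stated",
    "metrics": [
      {"unit": "admissions", "actual": 7217}
    ],
    "outcome_note": "6,595 active clients; 7,938 referrals; 1,987 transitions to other care; increase from prior years noted",
    "source_note": "Pages 52-54: Admissions and clients."
  },
  {
    "program": "Recovery Communities",
    "planned_description": "Establish 11 sites (5 Indigenous partnerships); add ~700 beds to serve up to 2,000 Albertans/year; $24M (Red Deer), $19M (Lethbridge)",
    "metrics": [
      {"unit": "clients", "planned": 2000, "actual": 219},
      {"unit": "beds", "planned": 700, "actual": 125}
    ],
    "outcome_note": "2 sites opened (Red Deer: 75 beds, 145 clients; Lethbridge: 50 beds, 74 clients); 2 more under construction",
    "source_note": "Pages 29-31, 35-36: Clients served; beds operational by March 2024."
  },
  {
    "program": "Tele-Mental Health (Counselling Alberta)",
    "planned_description": "$3.7M funding for expansion (toward $6.9M over 3 years); add 14 counsellors; expand to rural/in-person sites; no numeric session target stated",
    "metrics": [
      {"unit": "sessions", "actual": 12300, "approximate": true}
    ],
    "outcome_note": ">2,150 unique clients (95% reported improvement); services to 13 additional communities",
    "source_note": "Pages 53-54: Sessions and clients; significant increase from 2022-23."
  }
]
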