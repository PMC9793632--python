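{
  "description": "Preconfigured goal, intervention, and measure templates with goal-linked intervention suggestions. The four linked goals and their suggested interventions follow the shipped app library; the remaining general entries are this package's own examples. Reminder defaults (daily, one time of day) are editable after instantiation.",
  "goals": [
    {"name": "Reduce back pain", "rationale": "Less pain in everyday activities"},
    {"name": "Treat leg cramps", "rationale": "Fewer and milder cramps, especially at night"},
    {"name": "Treat rheumatoid arthritis", "rationale": "Reduce joint pain and stiffness"},
    {"name": "Treat irritable bowel syndrome", "rationale": "Fewer digestive complaints"},
    {"name": "Improve sleep", "rationale": "Fall asleep faster and feel rested"},
    {"name": "Increase energy", "rationale": "Feel less tired during the day"}
  ],
  "interventions": [
    {"name": "Willow bark tea", "instructions": "Drink one cup of willow bark tea.", "reminder": {"times": ["08:00"], "recurrence": "daily"}},
    {"name": "Arnica gel", "instructions": "Apply arnica gel to the painful area.", "reminder": {"times": ["20:00"], "recurrence": "daily"}},
    {"name": "Warming pad", "instructions": "Use a warming pad on your back for 20 minutes.", "reminder": {"times": ["20:00"], "recurrence": "daily"}},
    {"name": "Magnesium", "instructions": "Take a magnesium supplement with a meal.", "reminder": {"times": ["19:00"], "recurrence": "daily"}},
    {"name": "Vitamin B12", "instructions": "Take a vitamin B12 supplement.", "reminder": {"times": ["08:00"], "recurrence": "daily"}},
    {"name": "Massage", "instructions": "Massage the affected muscles for 10 minutes.", "reminder": {"times": ["21:00"], "recurrence": "daily"}},
    {"name": "Omega-3 supplement", "instructions": "Take an omega-3 supplement with a meal.", "reminder": {"times": ["12:00"], "recurrence": "daily"}},
    {"name": "Olive oil massage", "instructions": "Gently massage the affected joints with olive oil.", "reminder": {"times": ["20:00"], "recurrence": "daily"}},
    {"name": "Cold patch", "instructions": "Apply a cold patch to the affected joint for 15 minutes.", "reminder": {"times": ["18:00"], "recurrence": "daily"}},
    {"name": "Gluten-free diet", "instructions": "Avoid foods containing gluten today.", "reminder": {"times": ["09:00"], "recurrence": "daily"}},
    {"name": "Fructose-free diet", "instructions": "Avoid foods high in fructose today.", "reminder": {"times": ["09:00"], "recurrence": "daily"}},
    {"name": "Low-fiber diet", "instructions": "Choose low-fiber foods today.", "reminder": {"times": ["09:00"], "recurrence": "daily"}},
    {"name": "Going for a walk", "instructions": "Take a 30-minute walk outside.", "reminder": {"times": ["17:00"], "recurrence": "daily"}},
    {"name": "Meditation", "instructions": "Do a 10-minute guided meditation.", "reminder": {"times": ["07:30"], "recurrence": "daily"}},
    {"name": "Stretching", "instructions": "Do 10 minutes of gentle stretching.", "reminder": {"times": ["18:30"], "recurrence": "daily"}}
  ],
  "measures": [
    {"name": "Pain level", "input_type": "scale", "scale_config": {"min": 0, "max": 10, "annotations": [{"position": 0, "label": "no pain"}, {"position": 10, "label": "worst imaginable pain"}]}, "reminder": {"times": ["21:00"], "recurrence": "daily"}},
    {"name": "Sleep duration", "input_type": "keyboard", "keyboard_config": {"unit": "hours"}, "reminder": {"times": ["08:00"], "recurrence": "daily"}},
    {"name": "Mood", "input_type": "list", "list_config": {"items": ["very bad", "bad", "neutral", "good", "very good"]}, "reminder": {"times": ["20:00"], "recurrence": "daily"}},
    {"name": "Symptoms occurred", "input_type": "list", "list_config": {"items": ["yes", "no"]}, "reminder": {"times": ["21:30"], "recurrence": "daily"}},
    {"name": "Energy level", "input_type": "scale", "scale_config": {"min": 0, "max": 10, "annotations": [{"position": 0, "label": "exhausted"}, {"position": 10, "label": "full of energy"}]}, "reminder": {"times": ["14:00"], "recurrence": "daily"}}
  ],
  "links": {
    "Reduce back pain": ["Willow bark tea", "Arnica gel", "Warming pad"],
    "Treat leg cramps": ["Magnesium", "Vitamin B12", "Massage"],
    "Treat rheumatoid arthritis": ["Omega-3 supplement", "Olive oil massage", "Cold patch"],
    "Treat irritable bowel syndrome": ["Gluten-free diet", "Fructose-free diet", "Low-fiber diet"]
  }
}
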