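{
  "description": "Etymologically established language groups used as ground-truth clades for the 69-language Eurasian sample. 'Altaic' is contested and typically excluded from scoring.",
  "groups": [
    {"name": "Sinitic", "members": ["Mandarin", "Cantonese"]},
    {"name": "Dravidian", "members": ["Tamil", "Telugu"]},
    {"name": "Basque", "members": ["Basque_Central", "Basque_Western"]},
    {"name": "Uralic", "members": ["Mari_1", "Mari_2", "Udmurt_1", "Udmurt_2", "Hungarian", "Khanty_1", "Khanty_2", "Estonian", "Finnish"]},
    {"name": "Altaic", "members": ["Kazakh", "Kirghiz", "Turkish", "Yakut", "Uzbek", "Evenki", "Even_1", "Even_2", "Buryat"]},
    {"name": "IE", "members": ["Irish", "Welsh", "Marathi", "Hindi", "Pashto", "Greek", "Greek_Cypriot", "Greek_Calabria_1", "Greek_Calabria_2", "Greek_Salento", "Bulgarian", "Serbo-Croatian", "Slovenian", "Polish", "Russian", "Faroese", "Norwegian", "Danish", "Icelandic", "German", "Dutch", "English", "Afrikaans", "French", "Casalasco", "Reggio_Emilia", "Parma", "Spanish", "Portuguese", "Romanian", "Siciliano_Ragusa", "Siciliano_Mussomeli", "Salentino", "Calabrese_Southern", "Italian", "Barese", "Campano", "Teramano", "Calabrese_Northern"]},
    {"name": "NE-Caucasian", "members": ["Archi", "Lak"]},
    {"name": "Balto-Finnic", "members": ["Estonian", "Finnish"]},
    {"name": "Ugric", "members": ["Hungarian", "Khanty_1", "Khanty_2"]},
    {"name": "Turkic", "members": ["Kazakh", "Kirghiz", "Turkish", "Yakut", "Uzbek"]},
    {"name": "Tungusic", "members": ["Evenki", "Even_1", "Even_2"]},
    {"name": "Kipchak", "members": ["Kazakh", "Kirghiz"]},
    {"name": "Celtic", "members": ["Irish", "Welsh"]},
    {"name": "Indo-Iranian", "members": ["Hindi", "Marathi", "Pashto"]},
    {"name": "Greek", "members": ["Greek", "Greek_Cypriot", "Greek_Calabria_1", "Greek_Calabria_2", "Greek_Salento"]},
    {"name": "Slavic", "members": ["Bulgarian", "Serbo-Croatian", "Slovenian", "Polish", "Russian"]},
    {"name": "Germanic", "members": ["Faroese", "Norwegian", "Danish", "Icelandic", "German", "Dutch", "English", "Afrikaans"]},
    {"name": "Romance", "members": ["French", "Spanish", "Portuguese", "Romanian", "Italian", "Casalasco", "Parma", "Reggio_Emilia", "Siciliano_Ragusa", "Siciliano_Mussomeli", "Salentino", "Calabrese_Southern", "Barese", "Campano", "Teramano", "Calabrese_Northern"]},
    {"name": "Indo-Aryan", "members": ["Hindi", "Marathi"]},
    {"name": "South-Slavic", "members": ["Bulgarian", "Serbo-Croatian", "Slovenian"]},
    {"name": "North Germanic", "members": ["Faroese", "Norwegian", "Danish", "Icelandic"]},
    {"name": "West Germanic", "members": ["German", "Dutch", "Afrikaans", "English"]},
    {"name": "Continental West-Germanic", "members": ["German", "Dutch", "Afrikaans"]},
    {"name": "Ibero-Romance", "members": ["Spanish", "Portuguese"]}
  ]
}
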