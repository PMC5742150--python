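"""Generate the best-effort world land-border graph fixture (world.col).

Hand-assembled approximation of the UN member-state land-border list;
island states without land borders appear as isolated vertices.
"""
import sys
sys.path.insert(0, "src")  # run from the repository root

EDGES = """
Canada USA
USA Mexico
Mexico Guatemala
Mexico Belize
Guatemala Belize
Guatemala Honduras
Guatemala El_Salvador
Honduras El_Salvador
Honduras Nicaragua
Nicaragua Costa_Rica
Costa_Rica Panama
Panama Colombia
Haiti Dominican_Republic
Colombia Venezuela
Colombia Ecuador
Colombia Peru
Colombia Brazil
Venezuela Guyana
Venezuela Brazil
Guyana Suriname
Guyana Brazil
Suriname Brazil
Ecuador Peru
Peru Brazil
Peru Bolivia
Peru Chile
Bolivia Brazil
Bolivia Chile
Bolivia Paraguay
Bolivia Argentina
Paraguay Brazil
Paraguay Argentina
Brazil Argentina
Brazil Uruguay
Argentina Uruguay
Argentina Chile
Portugal Spain
Spain France
Spain Andorra
France Andorra
France Belgium
France Luxembourg
France Germany
France Switzerland
France Italy
France Monaco
Belgium Netherlands
Belgium Luxembourg
Belgium Germany
Netherlands Germany
Luxembourg Germany
Germany Denmark
Germany Poland
Germany Czechia
Germany Austria
Germany Switzerland
Switzerland Italy
Switzerland Austria
Switzerland Liechtenstein
Austria Liechtenstein
Austria Italy
Austria Slovenia
Austria Hungary
Austria Slovakia
Austria Czechia
Italy Slovenia
Italy San_Marino
Slovenia Croatia
Slovenia Hungary
Croatia Hungary
Croatia Serbia
Croatia Bosnia_Herzegovina
Croatia Montenegro
Bosnia_Herzegovina Serbia
Bosnia_Herzegovina Montenegro
Montenegro Serbia
Montenegro Albania
Serbia Hungary
Serbia Romania
Serbia Bulgaria
Serbia North_Macedonia
Albania Greece
Albania North_Macedonia
North_Macedonia Greece
North_Macedonia Bulgaria
Greece Bulgaria
Greece Turkey
Bulgaria Romania
Bulgaria Turkey
Romania Hungary
Romania Ukraine
Romania Moldova
Moldova Ukraine
Hungary Slovakia
Hungary Ukraine
Slovakia Czechia
Slovakia Poland
Slovakia Ukraine
Poland Czechia
Poland Ukraine
Poland Belarus
Poland Lithuania
Poland Russia
Lithuania Latvia
Lithuania Belarus
Lithuania Russia
Latvia Estonia
Latvia Russia
Latvia Belarus
Estonia Russia
Belarus Russia
Belarus Ukraine
Ukraine Russia
Finland Sweden
Finland Norway
Finland Russia
Sweden Norway
Norway Russia
Ireland United_Kingdom
Morocco Algeria
Morocco Mauritania
Algeria Tunisia
Algeria Libya
Algeria Niger
Algeria Mali
Algeria Mauritania
Tunisia Libya
Libya Egypt
Libya Sudan
Libya Chad
Libya Niger
Egypt Sudan
Egypt Israel
Sudan Chad
Sudan Central_African_Republic
Sudan South_Sudan
Sudan Ethiopia
Sudan Eritrea
South_Sudan Ethiopia
South_Sudan Kenya
South_Sudan Uganda
South_Sudan DR_Congo
South_Sudan Central_African_Republic
Eritrea Ethiopia
Eritrea Djibouti
Ethiopia Djibouti
Ethiopia Somalia
Ethiopia Kenya
Djibouti Somalia
Somalia Kenya
Kenya Uganda
Kenya Tanzania
Uganda Tanzania
Uganda Rwanda
Uganda DR_Congo
Rwanda Tanzania
Rwanda Burundi
Rwanda DR_Congo
Burundi Tanzania
Burundi DR_Congo
Tanzania Zambia
Tanzania Malawi
Tanzania Mozambique
DR_Congo Congo_Republic
DR_Congo Central_African_Republic
DR_Congo Angola
DR_Congo Zambia
Congo_Republic Gabon
Congo_Republic Cameroon
Congo_Republic Central_African_Republic
Congo_Republic Angola
Gabon Cameroon
Gabon Equatorial_Guinea
Cameroon Equatorial_Guinea
Cameroon Nigeria
Cameroon Chad
Cameroon Central_African_Republic
Chad Niger
Chad Nigeria
Chad Central_African_Republic
Niger Nigeria
Niger Mali
Niger Burkina_Faso
Niger Benin
Nigeria Benin
Benin Togo
Benin Burkina_Faso
Togo Ghana
Togo Burkina_Faso
Ghana Burkina_Faso
Ghana Ivory_Coast
Burkina_Faso Mali
Burkina_Faso Ivory_Coast
Ivory_Coast Mali
Ivory_Coast Guinea
Ivory_Coast Liberia
Mali Mauritania
Mali Senegal
Mali Guinea
Mauritania Senegal
Senegal Gambia
Senegal Guinea_Bissau
Senegal Guinea
Guinea_Bissau Guinea
Guinea Liberia
Guinea Sierra_Leone
Sierra_Leone Liberia
Angola Zambia
Angola Namibia
Zambia Malawi
Zambia Mozambique
Zambia Zimbabwe
Zambia Botswana
Zambia Namibia
Malawi Mozambique
Mozambique Zimbabwe
Mozambique South_Africa
Mozambique Eswatini
Zimbabwe Botswana
Zimbabwe South_Africa
Botswana Namibia
Botswana South_Africa
Namibia South_Africa
South_Africa Lesotho
South_Africa Eswatini
Turkey Georgia
Turkey Armenia
Turkey Azerbaijan
Turkey Iran
Turkey Iraq
Turkey Syria
Syria Lebanon
Syria Israel
Syria Jordan
Syria Iraq
Lebanon Israel
Israel Jordan
Jordan Iraq
Jordan Saudi_Arabia
Iraq Iran
Iraq Kuwait
Iraq Saudi_Arabia
Kuwait Saudi_Arabia
Saudi_Arabia Qatar
Saudi_Arabia UAE
Saudi_Arabia Oman
Saudi_Arabia Yemen
UAE Oman
Oman Yemen
Iran Armenia
Iran Azerbaijan
Iran Turkmenistan
Iran Afghanistan
Iran Pakistan
Georgia Russia
Georgia Armenia
Georgia Azerbaijan
Armenia Azerbaijan
Azerbaijan Russia
Russia Kazakhstan
Russia Mongolia
Russia China
Russia North_Korea
Kazakhstan Uzbekistan
Kazakhstan Turkmenistan
Kazakhstan Kyrgyzstan
Kazakhstan China
Uzbekistan Turkmenistan
Uzbekistan Kyrgyzstan
Uzbekistan Tajikistan
Uzbekistan Afghanistan
Turkmenistan Afghanistan
Kyrgyzstan Tajikistan
Kyrgyzstan China
Tajikistan Afghanistan
Tajikistan China
Afghanistan Pakistan
Afghanistan China
Pakistan China
Pakistan India
China India
China Nepal
China Bhutan
China Mongolia
China Myanmar
China Laos
China Vietnam
China North_Korea
India Nepal
India Bhutan
India Bangladesh
India Myanmar
Bangladesh Myanmar
Myanmar Thailand
Myanmar Laos
Thailand Laos
Thailand Cambodia
Thailand Malaysia
Laos Vietnam
Laos Cambodia
Cambodia Vietnam
Malaysia Indonesia
Malaysia Brunei
Indonesia Papua_New_Guinea
Indonesia Timor_Leste
North_Korea South_Korea
"""

ISOLATED = """
Iceland Malta Cyprus Cuba Jamaica Bahamas Barbados Trinidad_Tobago Grenada
St_Lucia St_Vincent Antigua_Barbuda St_Kitts_Nevis Dominica Cape_Verde
Sao_Tome_Principe Comoros Seychelles Mauritius Madagascar Maldives Sri_Lanka
Japan Philippines Singapore Fiji Vanuatu Solomon_Islands Samoa Tonga Kiribati
Tuvalu Nauru Palau Marshall_Islands Micronesia New_Zealand Australia
""".split()

edges = [tuple(line.split()) for line in EDGES.strip().splitlines()]
vertices = []
for u, v in edges:
    for w in (u, v):
        if w not in vertices:
            vertices.append(w)
for w in ISOLATED:
    if w not in vertices:
        vertices.append(w)

from spikesat.io import write_dimacs_col  # noqa: E402

write_dimacs_col(
    "src/spikesat/data/world.col", vertices, edges,
    comment=("World map 4-coloring instance.\n"
             "Best-effort reconstruction of the UN member land-border list;\n"
             "island states without land borders are isolated vertices."))
print(f"{len(vertices)} vertices, {len(edges)} edges")
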