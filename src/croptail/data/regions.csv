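country,region
Argentina,South America
Bolivia,South America
Brazil,South America
Chile,South America
Colombia,South America
Ecuador,South America
Guyana,South America
Paraguay,South America
Peru,South America
Suriname,South America
Uruguay,South America
Venezuela,South America
Belize,Central America & Caribbean
Costa Rica,Central America & Caribbean
Cuba,Central America & Caribbean
Dominican Republic,Central America & Caribbean
El Salvador,Central America & Caribbean
Guatemala,Central America & Caribbean
Haiti,Central America & Caribbean
Honduras,Central America & Caribbean
Jamaica,Central America & Caribbean
Mexico,Central America & Caribbean
Nicaragua,Central America & Caribbean
Panama,Central America & Caribbean
Trinidad and Tobago,Central America & Caribbean
Benin,Western Africa
Burkina Faso,Western Africa
The Gambia,Western Africa
Ghana,Western Africa
Guinea,Western Africa
Ivory Coast,Western Africa
Liberia,Western Africa
Mali,Western Africa
Mauritania,Western Africa
Niger,Western Africa
Nigeria,Western Africa
Senegal,Western Africa
Sierra Leone,Western Africa
Togo,Western Africa
Burundi,Eastern Africa
Comoros,Eastern Africa
Djibouti,Eastern Africa
Eritrea,Eastern Africa
Ethiopia,Eastern Africa
Kenya,Eastern Africa
Madagascar,Eastern Africa
Malawi,Eastern Africa
Mozambique,Eastern Africa
Rwanda,Eastern Africa
Somalia,Eastern Africa
Sudan,Eastern Africa
Uganda,Eastern Africa
United Republic of Tanzania,Eastern Africa
Zambia,Eastern Africa
Zimbabwe,Eastern Africa
Angola,Middle & Southern Africa
Botswana,Middle & Southern Africa
Cameroon,Middle & Southern Africa
Central African Republic,Middle & Southern Africa
Chad,Middle & Southern Africa
Congo,Middle & Southern Africa
Gabon,Middle & Southern Africa
Lesotho,Middle & Southern Africa
Namibia,Middle & Southern Africa
South Africa,Middle & Southern Africa
Swaziland,Middle & Southern Africa
Bangladesh,South & South-Eastern Asia & Melanesia
Brunei,South & South-Eastern Asia & Melanesia
Bhutan,South & South-Eastern Asia & Melanesia
Cambodia,South & South-Eastern Asia & Melanesia
Indonesia,South & South-Eastern Asia & Melanesia
India,South & South-Eastern Asia & Melanesia
Fiji,South & South-Eastern Asia & Melanesia
Laos,South & South-Eastern Asia & Melanesia
Malaysia,South & South-Eastern Asia & Melanesia
Myanmar,South & South-Eastern Asia & Melanesia
New Caledonia,South & South-Eastern Asia & Melanesia
Papua New Guinea,South & South-Eastern Asia & Melanesia
Philippines,South & South-Eastern Asia & Melanesia
Solomon Is.,South & South-Eastern Asia & Melanesia
Thailand,South & South-Eastern Asia & Melanesia
Vanuatu,South & South-Eastern Asia & Melanesia
Vietnam,South & South-Eastern Asia & Melanesia
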